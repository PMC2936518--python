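"""Seeded synthetic benchmark fixtures with a planted SL signal.

The generator emulates the data landscape of a yeast synthetic-lethality
study: genes are partitioned into functional modules, and every data
source — weighted networks, expression, pathway memberships,
phylogenetic profiles, a toy GO tree with gene annotations — reflects
module structure with tunable noise.  Labels are then planted so that
the probability of a pair being SL is boosted for same-module pairs by
``signal_strength`` over the baseline, while the overall positive
fraction is held at the configured class skew (7.1% by default, the
skew of curated yeast SL collections).  At signal_strength 0 the labels
are independent of every data source, giving an exact null.

Module-based planting (rather than, say, degree-based) matches the
empirical finding that co-membership and functional-similarity feature
families are the most discriminative for this problem.

Everything is deterministic under the seed: genes, pairs and candidate
edges are enumerated in sorted order and sampled by integer index.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .features import SemSimSource, read_gmt
from .go_semantics import AnnotationSet, Ontology, term_probabilities
from .networks import GenePair, WeightedNetwork, read_edge_list, write_edge_list

__all__ = ["FixtureConfig", "SyntheticBundle", "generate_fixture", "generate_toy_ontology"]


@dataclass
class FixtureConfig:
    """Study conditions for a synthetic benchmark.

    The defaults describe a down-scaled but structurally faithful
    setting: a few hundred genes in functional modules, four weighted
    networks of differing reliability, ~7% positive pairs, and a strong
    but imperfect coupling between module co-membership and lethality.
    """

    n_genes: int = 300
    n_modules: int = 15
    n_networks: int = 4
    within_module_edge_prob: float = 0.35
    background_edge_prob: float = 0.01
    within_weight: tuple[float, float] = (0.5, 1.0)
    background_weight: tuple[float, float] = (0.05, 0.6)
    n_expression_samples: int = 40
    expression_module_corr: float = 0.7
    n_phylo_organisms: int = 24
    phylo_flip_prob: float = 0.15
    membership_noise_prob: float = 0.05
    n_pairs: int = 2000
    positive_fraction: float = 0.071
    same_module_pair_fraction: float = 0.12
    signal_strength: float = 0.8
    max_within_sl_prob: float = 0.5
    ontology_depth: int = 3
    ontology_branching: int = 3
    annotations_per_gene: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "within_module_edge_prob",
            "background_edge_prob",
            "positive_fraction",
            "same_module_pair_fraction",
            "signal_strength",
            "phylo_flip_prob",
            "membership_noise_prob",
            "expression_module_corr",
            "max_within_sl_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_modules > self.n_genes:
            raise ValueError("n_modules cannot exceed n_genes")
        # feasibility of the planted skew (see _pair_probabilities)
        self._pair_probabilities()

    def _pair_probabilities(self) -> tuple[float, float]:
        """P(SL | same module) and P(SL | different module).

        p_same interpolates from the baseline skew q (signal 0) to
        ``max_within_sl_prob`` (signal 1); p_diff compensates so that
        the marginal positive fraction stays exactly q.
        """
        q = self.positive_fraction
        f = self.same_module_pair_fraction
        p_same = q + self.signal_strength * (self.max_within_sl_prob - q)
        if f >= 1.0:
            raise ValueError("same_module_pair_fraction must be < 1")
        p_diff = (q - f * p_same) / (1.0 - f)
        if p_diff < 0 or p_diff > 1:
            raise ValueError(
                f"positive_fraction {q} infeasible with same-module SL "
                f"probability {p_same:.3f} at pair fraction {f}"
            )
        return p_same, p_diff


@dataclass
class SyntheticBundle:
    """A complete generated study: data sources plus labelled pairs."""

    config: FixtureConfig
    genes: list[str]
    module_of: dict[str, int]
    networks: list[WeightedNetwork]
    expression: pd.DataFrame          # genes x samples
    memberships: dict[str, set[str]]  # gene -> pathway ids
    profiles: pd.DataFrame            # genes x organisms, binary
    ontology: Ontology
    annotations: AnnotationSet
    pairs: list[GenePair]
    labels: pd.Series                 # aligned with pairs; 1 = SL


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def generate_toy_ontology(
    depth: int,
    branching: int,
    n_genes: int,
    seed: int,
    module_of: Optional[dict[str, int]] = None,
    annotations_per_gene: int = 3,
    genes: Optional[list[str]] = None,
) -> tuple[Ontology, AnnotationSet]:
    """A complete rooted tree ontology with leaf-level gene annotations.

    The tree has ``branching``^``depth`` leaves under one biological-
    process root.  Each gene is annotated to ``annotations_per_gene``
    leaves; when ``module_of`` is given, a gene's first annotation is
    its module's designated leaf, so module-mates share specific terms
    and their semantic similarity exceeds that of non-mates.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    parents: dict[str, set[str]] = {_term_id(0): set()}
    namespace: dict[str, str] = {_term_id(0): "biological_process"}
    level = [_term_id(0)]
    counter = 1
    for _ in range(depth):
        nxt = []
        for parent in level:
            for _ in range(branching):
                t = _term_id(counter)
                counter += 1
                parents[t] = {parent}
                namespace[t] = "biological_process"
                nxt.append(t)
        level = nxt
    leaves = level
    onto = Ontology(parents, namespace)

    rng = np.random.default_rng(seed)
    if genes is None:
        genes = _gene_names(n_genes)
    ann = AnnotationSet()
    for g in sorted(genes):
        chosen: set[str] = set()
        if module_of is not None and g in module_of:
            chosen.add(leaves[module_of[g] % len(leaves)])
        while len(chosen) < min(annotations_per_gene, len(leaves)):
            chosen.add(leaves[int(rng.integers(len(leaves)))])
        for t in sorted(chosen):
            ann.add(g, t)
    return onto, ann


def _gen_network(
    idx: int,
    genes: list[str],
    module_of: dict[str, int],
    cfg: FixtureConfig,
    rng: np.random.Generator,
) -> WeightedNetwork:
    net = WeightedNetwork(name=f"net{idx}")
    lo_w, hi_w = cfg.within_weight
    lo_b, hi_b = cfg.background_weight
    for a, b in itertools.combinations(genes, 2):
        same = module_of[a] == module_of[b]
        p = cfg.within_module_edge_prob if same else cfg.background_edge_prob
        if rng.random() < p:
            if same:
                w = lo_w + (hi_w - lo_w) * rng.random()
            else:
                w = lo_b + (hi_b - lo_b) * rng.random()
            net.add_edge(a, b, round(float(w), 6))
    return net


def _gen_expression(
    genes: list[str],
    module_of: dict[str, int],
    cfg: FixtureConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rho = cfg.expression_module_corr
    factors = rng.normal(size=(cfg.n_modules, cfg.n_expression_samples))
    rows = []
    for g in genes:
        noise = rng.normal(size=cfg.n_expression_samples)
        rows.append(math.sqrt(rho) * factors[module_of[g]] + math.sqrt(1 - rho) * noise)
    cols = [f"S{i:03d}" for i in range(cfg.n_expression_samples)]
    df = pd.DataFrame(np.round(np.asarray(rows), 6), index=genes, columns=cols)
    df.index.name = "gene"
    return df


def _gen_memberships(
    genes: list[str],
    module_of: dict[str, int],
    cfg: FixtureConfig,
    rng: np.random.Generator,
) -> dict[str, set[str]]:
    membership: dict[str, set[str]] = {}
    for g in genes:
        groups = {f"PW{module_of[g]:03d}"}
        for m in range(cfg.n_modules):
            if m != module_of[g] and rng.random() < cfg.membership_noise_prob:
                groups.add(f"PW{m:03d}")
        membership[g] = groups
    return membership


def _gen_profiles(
    genes: list[str],
    module_of: dict[str, int],
    cfg: FixtureConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    base = rng.integers(0, 2, size=(cfg.n_modules, cfg.n_phylo_organisms))
    rows = []
    for g in genes:
        flips = rng.random(cfg.n_phylo_organisms) < cfg.phylo_flip_prob
        rows.append(np.where(flips, 1 - base[module_of[g]], base[module_of[g]]))
    cols = [f"ORG{i:02d}" for i in range(cfg.n_phylo_organisms)]
    df = pd.DataFrame(np.asarray(rows, dtype=int), index=genes, columns=cols)
    df.index.name = "gene"
    return df


def _gen_pairs_labels(
    genes: list[str],
    module_of: dict[str, int],
    cfg: FixtureConfig,
    rng: np.random.Generator,
) -> tuple[list[GenePair], pd.Series]:
    all_pairs = list(itertools.combinations(genes, 2))
    same = [p for p in all_pairs if module_of[p[0]] == module_of[p[1]]]
    diff = [p for p in all_pairs if module_of[p[0]] != module_of[p[1]]]
    n_same = round(cfg.same_module_pair_fraction * cfg.n_pairs)
    n_diff = cfg.n_pairs - n_same
    if n_same > len(same) or n_diff > len(diff):
        raise ValueError(
            f"cannot draw {n_same} same-module / {n_diff} cross-module pairs "
            f"from {len(same)} / {len(diff)} available"
        )
    pick_same = rng.choice(len(same), size=n_same, replace=False)
    pick_diff = rng.choice(len(diff), size=n_diff, replace=False)
    chosen = [same[i] for i in sorted(pick_same)] + [diff[i] for i in sorted(pick_diff)]

    # exact positive counts: overall count is round(q * n_pairs); the
    # same-module share of positives follows the planted boost
    q = cfg.positive_fraction
    p_same, p_diff = cfg._pair_probabilities()
    n_pos = round(q * cfg.n_pairs)
    n_pos_same = min(n_same, round(n_pos * (n_same * p_same) / (n_same * p_same + n_diff * p_diff)))
    n_pos_diff = n_pos - n_pos_same
    if n_pos_diff > n_diff:
        raise ValueError("infeasible positive allocation")
    pos_same_idx = set(rng.choice(n_same, size=n_pos_same, replace=False).tolist())
    pos_diff_idx = set((n_same + rng.choice(n_diff, size=n_pos_diff, replace=False)).tolist())
    labels = np.zeros(cfg.n_pairs, dtype=int)
    for i in pos_same_idx | pos_diff_idx:
        labels[i] = 1

    # shuffle presentation order deterministically
    perm = rng.permutation(cfg.n_pairs)
    pairs = [GenePair(*chosen[i]) for i in perm]
    y = pd.Series(
        labels[perm],
        index=pd.MultiIndex.from_tuples([(p.a, p.b) for p in pairs], names=["geneA", "geneB"]),
        name="label",
    )
    return pairs, y


def generate_fixture(config: FixtureConfig) -> SyntheticBundle:
    """Generate the full study bundle for the given conditions.

    Identical configs (including the seed) produce identical bundles.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(7)
    rng_modules, rng_nets, rng_expr, rng_memb, rng_phylo, rng_pairs, rng_onto = (
        np.random.default_rng(s) for s in streams
    )

    genes = _gene_names(cfg.n_genes)
    assignment = rng_modules.integers(0, cfg.n_modules, size=cfg.n_genes)
    module_of = {g: int(m) for g, m in zip(genes, assignment)}

    networks = [
        _gen_network(i, genes, module_of, cfg, rng_nets) for i in range(cfg.n_networks)
    ]
    expression = _gen_expression(genes, module_of, cfg, rng_expr)
    memberships = _gen_memberships(genes, module_of, cfg, rng_memb)
    profiles = _gen_profiles(genes, module_of, cfg, rng_phylo)
    onto_seed = int(streams[6].generate_state(1)[0] & 0x7FFFFFFF)
    ontology, annotations = generate_toy_ontology(
        cfg.ontology_depth,
        cfg.ontology_branching,
        cfg.n_genes,
        onto_seed,
        module_of=module_of,
        annotations_per_gene=cfg.annotations_per_gene,
        genes=genes,
    )
    pairs, labels = _gen_pairs_labels(genes, module_of, cfg, rng_pairs)
    return SyntheticBundle(
        config=cfg,
        genes=genes,
        module_of=module_of,
        networks=networks,
        expression=expression,
        memberships=memberships,
        profiles=profiles,
        ontology=ontology,
        annotations=annotations,
        pairs=pairs,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# default feature pipeline over a bundle
# ---------------------------------------------------------------------------

def default_catalog_and_sources(bundle: SyntheticBundle):
    """The standard feature catalog for a generated bundle.

    Direct features: one edge-weight feature per network, co-expression
    correlation, TOM on the first network, pathway co-membership,
    phylogenetic-profile MI and GO BP semantic similarity; overlay
    features for every unordered pair of the generated networks.
    """
    from .features import FeatureSpec, build_overlay_catalog

    net_names = [n.name for n in bundle.networks]
    probs = term_probabilities(bundle.ontology, bundle.annotations)
    sources: dict[str, object] = {n.name: n for n in bundle.networks}
    sources["expression"] = bundle.expression
    sources["memberships"] = bundle.memberships
    sources["profiles"] = bundle.profiles
    sources["semsim_bp"] = SemSimSource(
        bundle.ontology, bundle.annotations, probs, "biological_process"
    )
    catalog = [
        FeatureSpec(f"direct_{n}", "direct", (n,), "edge_weight") for n in net_names
    ]
    catalog += [
        FeatureSpec("coexpression", "direct", ("expression",), "correlation"),
        FeatureSpec(f"tom_{net_names[0]}", "direct", (net_names[0],), "tom"),
        FeatureSpec("pathway_comembership", "direct", ("memberships",), "comembership"),
        FeatureSpec("phylo_mi", "direct", ("profiles",), "phylo_mi"),
        FeatureSpec("semsim_bp", "direct", ("semsim_bp",), "semsim"),
    ]
    catalog += build_overlay_catalog(net_names)
    return catalog, sources


def fixture_feature_matrix(bundle: SyntheticBundle) -> pd.DataFrame:
    from .features import assemble_feature_matrix

    catalog, sources = default_catalog_and_sources(bundle)
    return assemble_feature_matrix(catalog, sources, bundle.pairs)


# ---------------------------------------------------------------------------
# writers / readers for every external format the pipeline consumes
# ---------------------------------------------------------------------------

def write_fixture(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write the bundle as edge lists, TSV, GMT, OBO, GAF and a manifest."""
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    for net in bundle.networks:
        write_edge_list(net, d / f"{net.name}.tsv")
    bundle.expression.rename_axis("gene").to_csv(d / "expression.tsv", sep="\t")
    bundle.profiles.rename_axis("gene").to_csv(d / "profiles.tsv", sep="\t")

    groups: dict[str, list[str]] = {}
    for g, gs in bundle.memberships.items():
        for grp in gs:
            groups.setdefault(grp, []).append(g)
    with open(d / "memberships.gmt", "w") as fh:
        for grp in sorted(groups):
            members = "\t".join(sorted(groups[grp]))
            fh.write(f"{grp}\tsynthetic module pathway\t{members}\n")

    _write_obo(bundle.ontology, d / "ontology.obo")
    _write_gaf(bundle.annotations, d / "annotations.gaf")

    with open(d / "pairs.tsv", "w") as fh:
        fh.write("geneA\tgeneB\tlabel\n")
        for p, lab in zip(bundle.pairs, bundle.labels.to_numpy()):
            fh.write(f"{p.a}\t{p.b}\t{'SL' if lab == 1 else 'nonSL'}\n")

    manifest = {"seed": bundle.config.seed, "config": asdict(bundle.config)}
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _write_obo(onto: Ontology, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-toy-go\n")
        for t in sorted(onto.terms):
            fh.write(f"\n[Term]\nid: {t}\nname: synthetic term {t}\n")
            fh.write(f"namespace: {onto.namespace[t]}\n")
            for p in sorted(onto.parents[t]):
                fh.write(f"is_a: {p} ! parent\n")


def _write_gaf(ann: AnnotationSet, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for g in sorted(ann.direct):
            for t in sorted(ann.direct[g]):
                cols = [
                    "SYN", g, g, "", t, "SYN:0001", "IEA", "", "P",
                    "", "", "gene", "taxon:0", "20200101", "SYN", "", "",
                ]
                fh.write("\t".join(cols) + "\n")


def read_labeled_pairs(path: str | Path) -> tuple[list[GenePair], pd.Series]:
    """Read a labelled pair TSV (geneA, geneB, label in {SL, nonSL})."""
    df = pd.read_csv(path, sep="\t")
    pairs = [GenePair(a, b) for a, b in zip(df["geneA"], df["geneB"])]
    y = pd.Series(
        (df["label"] == "SL").astype(int).to_numpy(),
        index=pd.MultiIndex.from_tuples([(p.a, p.b) for p in pairs], names=["geneA", "geneB"]),
        name="label",
    )
    return pairs, y


def read_fixture_dir(directory: str | Path):
    """Read a written fixture back into pipeline-ready objects.

    Returns (networks, expression, memberships, profiles, ontology,
    annotations, pairs, labels) — the same objects a fresh bundle would
    provide, reconstructed purely from the on-disk formats.
    """
    from .go_semantics import load_annotations, load_ontology

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    n_networks = manifest["config"]["n_networks"]
    networks = [read_edge_list(d / f"net{i}.tsv", name=f"net{i}") for i in range(n_networks)]
    expression = pd.read_csv(d / "expression.tsv", sep="\t", index_col="gene")
    profiles = pd.read_csv(d / "profiles.tsv", sep="\t", index_col="gene")
    memberships = read_gmt(d / "memberships.gmt")
    ontology = load_ontology(d / "ontology.obo")
    annotations = load_annotations(d / "annotations.gaf", ontology)
    pairs, labels = read_labeled_pairs(d / "pairs.tsv")
    return networks, expression, memberships, profiles, ontology, annotations, pairs, labels
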