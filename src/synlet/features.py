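"""Gene-pair feature computation.

Two families of features are computed for each candidate gene pair:

* *direct* features read a single data source — an edge weight, a
  co-expression correlation, a topological overlap, a co-membership
  count, phylogenetic-profile mutual information, or a GO functional
  similarity;
* *overlay* features combine two weighted networks, scoring a pair
  (A, B) by the strongest transitive link through any intermediate gene
  C: the maximum over C of the product of the A–C weight in one network
  and the C–B weight in the other (either leg may come from either
  network).  This is the weighted generalisation of the binary "2-hop"
  indicator.

Overlay features built with the known SL interaction network as one of
the inputs are *SL-dependent* and carry a distinct kind marker, because
inside cross-validation they must be recomputed from training-fold
positives only.

Missing values are first-class: an absent edge or an uncomputable
statistic yields NaN in the assembled matrix, never 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .go_semantics import (
    AnnotationSet,
    Ontology,
    gene_functional_similarity,
    shared_function_count,
)
from .networks import GenePair, WeightedNetwork

logger = logging.getLogger(__name__)

MISSING = float("nan")

__all__ = [
    "FeatureSpec",
    "overlay_value",
    "build_overlay_catalog",
    "build_sl_dependent_catalog",
    "coexpression_correlation",
    "topological_overlap",
    "comembership_count",
    "phylo_profile_mi",
    "assemble_feature_matrix",
    "SemSimSource",
    "SharedFunctionSource",
]


@dataclass(frozen=True)
class FeatureSpec:
    """A named pair-feature definition.

    kind is one of ``direct``, ``overlay`` or ``sl_dependent_overlay``;
    ``sources`` names the one (direct) or two (overlay) inputs; for
    direct features ``method`` selects the computation.
    """

    name: str
    kind: str
    sources: tuple[str, ...]
    method: str = ""

    def __post_init__(self) -> None:
        if self.kind not in {"direct", "overlay", "sl_dependent_overlay"}:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind != "direct" and len(self.sources) != 2:
            raise ValueError(f"{self.name}: overlay features need exactly 2 sources")


# ---------------------------------------------------------------------------
# overlay features
# ---------------------------------------------------------------------------

def overlay_value(
    n1: WeightedNetwork, n2: WeightedNetwork, pair: GenePair
) -> Optional[float]:
    """Strongest transitive link between the pair through two networks.

    max over intermediates C (C not in {A, B}) of
    ``w1(A,C) * w2(C,B)`` and ``w1(B,C) * w2(C,A)`` — both leg
    orderings are tried, so the value is symmetric in the two networks
    and in the pair's endpoints.  Returns None when no intermediate has
    both legs present.  The direct A–B edge never contributes; it is a
    separate direct feature.
    """
    a, b = pair.a, pair.b
    best: Optional[float] = None
    for first, second in ((n1, n2), (n2, n1)):
        na = first.neighbors(a)
        nb = second.neighbors(b)
        # iterate the smaller neighbourhood
        if len(na) <= len(nb):
            for c, w_ac in na.items():
                if c == b:
                    continue
                w_cb = nb.get(c)
                if w_cb is not None:
                    v = w_ac * w_cb
                    if best is None or v > best:
                        best = v
        else:
            for c, w_cb in nb.items():
                if c == a:
                    continue
                w_ac = na.get(c)
                if w_ac is not None:
                    v = w_ac * w_cb
                    if best is None or v > best:
                        best = v
    return best


def overlay_name(src1: str, src2: str) -> str:
    s1, s2 = sorted((src1, src2))
    return f"O({s1}, {s2})"


def build_overlay_catalog(
    input_networks: Sequence[str],
    exclusions: Iterable[tuple[str, str]] = (),
) -> list[FeatureSpec]:
    """One overlay spec per unordered pair of distinct networks.

    Self-overlays are never generated (their content lives in the direct
    features) and unordered name pairs in ``exclusions`` are skipped.
    With m networks and e exclusions the catalog has C(m, 2) - e specs.
    """
    names = list(input_networks)
    if len(names) < 2:
        raise ValueError("need at least 2 input networks for overlays")
    excl = {tuple(sorted(p)) for p in exclusions}
    known = set(names)
    for p in excl:
        for n in p:
            if n not in known:
                raise ValueError(f"exclusion references unknown network {n!r}")
    specs = []
    for s1, s2 in itertools.combinations(names, 2):
        if tuple(sorted((s1, s2))) in excl:
            continue
        specs.append(
            FeatureSpec(name=overlay_name(s1, s2), kind="overlay", sources=tuple(sorted((s1, s2))))
        )
    return specs


SL_NETWORK_NAME = "SL"


def build_sl_dependent_catalog(input_networks: Sequence[str]) -> list[FeatureSpec]:
    """Overlay specs pairing the known SL network with each input network,
    plus the SL-with-itself self-overlay.

    These are SL-*dependent*: inside cross-validation the SL network
    they reference is rebuilt from training-fold positives only.
    """
    specs = [
        FeatureSpec(
            name=overlay_name(SL_NETWORK_NAME, n),
            kind="sl_dependent_overlay",
            sources=(SL_NETWORK_NAME, n),
        )
        for n in input_networks
    ]
    specs.append(
        FeatureSpec(
            name=f"O({SL_NETWORK_NAME}, {SL_NETWORK_NAME})",
            kind="sl_dependent_overlay",
            sources=(SL_NETWORK_NAME, SL_NETWORK_NAME),
        )
    )
    return specs


# ---------------------------------------------------------------------------
# direct features
# ---------------------------------------------------------------------------

def coexpression_correlation(expr: pd.DataFrame, pair: GenePair) -> Optional[float]:
    """Pearson correlation of two genes' expression rows.

    Requires both genes present with >= 3 shared finite samples;
    otherwise the value is missing.  A zero-variance row yields missing
    (correlation undefined).
    """
    if pair.a not in expr.index or pair.b not in expr.index:
        return None
    x = expr.loc[pair.a].to_numpy(dtype=float)
    y = expr.loc[pair.b].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return None
    x, y = x[ok], y[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def topological_overlap(net: WeightedNetwork, pair: GenePair) -> Optional[float]:
    """Topological overlap measure of two nodes in a weighted network.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_k a_ik a_kj and k_i = sum_k a_ik, computed on absolute
    weights so adjacencies stay in [0, 1] for signed inputs.  Missing
    when either gene is absent from the network.
    """
    a, b = pair.a, pair.b
    na = net.neighbors(a)
    nb = net.neighbors(b)
    if not na or not nb:
        return None
    a_ij = abs(na.get(b, 0.0))
    l_ij = sum(
        abs(w) * abs(nb[c]) for c, w in na.items() if c in nb and c not in (a, b)
    )
    k_i = sum(abs(w) for w in na.values())
    k_j = sum(abs(w) for w in nb.values())
    denom = min(k_i, k_j) + 1.0 - a_ij
    if denom <= 0:
        return None
    return (l_ij + a_ij) / denom


def comembership_count(
    membership: Mapping[str, set[str]], pair: GenePair
) -> int:
    """Number of groups (pathways, complexes, communities) shared by the
    pair; 0 when either gene is unmapped."""
    ga = membership.get(pair.a)
    gb = membership.get(pair.b)
    if not ga or not gb:
        return 0
    return len(ga & gb)


def phylo_profile_mi(
    profiles: Mapping[str, np.ndarray] | pd.DataFrame, pair: GenePair
) -> Optional[float]:
    """Mutual information (nats) of two binary phylogenetic profiles.

    The joint 2x2 empirical distribution over organisms is used; a
    constant profile has zero entropy hence MI = 0.  Missing when either
    profile is absent; unequal lengths are an error.
    """
    if isinstance(profiles, pd.DataFrame):
        if pair.a not in profiles.index or pair.b not in profiles.index:
            return None
        x = profiles.loc[pair.a].to_numpy(dtype=int)
        y = profiles.loc[pair.b].to_numpy(dtype=int)
    else:
        if pair.a not in profiles or pair.b not in profiles:
            return None
        x = np.asarray(profiles[pair.a], dtype=int)
        y = np.asarray(profiles[pair.b], dtype=int)
    if x.shape != y.shape:
        raise ValueError(f"profile length mismatch for {pair}: {x.shape} vs {y.shape}")
    n = x.size
    mi = 0.0
    for vx in (0, 1):
        px = float(np.mean(x == vx))
        for vy in (0, 1):
            py = float(np.mean(y == vy))
            pxy = float(np.mean((x == vx) & (y == vy)))
            if pxy > 0 and px > 0 and py > 0:
                mi += pxy * math.log(pxy / (px * py))
    return max(mi, 0.0)


def neg_log_evalue(scores: Mapping[tuple[str, str], float], pair: GenePair, cap: float = 200.0) -> Optional[float]:
    """-log10 of a precomputed pairwise e-value, capped; missing if absent."""
    e = scores.get((pair.a, pair.b))
    if e is None:
        return None
    if e <= 0:
        return cap
    return min(-math.log10(e), cap)


# ---------------------------------------------------------------------------
# source wrappers for matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class SemSimSource:
    """Everything needed to score GO functional similarity for a pair."""

    ontology: Ontology
    annotations: AnnotationSet
    probs: Mapping[str, float]
    namespace: str = "biological_process"

    def value(self, pair: GenePair) -> Optional[float]:
        terms_a = {
            t
            for t in self.annotations.propagated(pair.a, self.ontology)
            if self.ontology.namespace[t] == self.namespace
        }
        terms_b = {
            t
            for t in self.annotations.propagated(pair.b, self.ontology)
            if self.ontology.namespace[t] == self.namespace
        }
        return gene_functional_similarity(terms_a, terms_b, self.probs, self.ontology)


@dataclass
class SharedFunctionSource:
    """Whitelist-restricted shared GO function count for a pair."""

    ontology: Ontology
    annotations: AnnotationSet
    whitelist: set[str]

    def value(self, pair: GenePair) -> float:
        return float(
            shared_function_count(
                pair.a, pair.b, self.annotations, self.ontology, self.whitelist
            )
        )


_DIRECT_METHODS = {
    "edge_weight",
    "correlation",
    "tom",
    "comembership",
    "phylo_mi",
    "semsim",
    "shared_functions",
    "pair_scores",
}


def _direct_value(spec: FeatureSpec, source, pair: GenePair) -> Optional[float]:
    m = spec.method
    if m == "edge_weight":
        return source.get(pair.a, pair.b)
    if m == "correlation":
        return coexpression_correlation(source, pair)
    if m == "tom":
        return topological_overlap(source, pair)
    if m == "comembership":
        return float(comembership_count(source, pair))
    if m == "phylo_mi":
        return phylo_profile_mi(source, pair)
    if m in ("semsim", "shared_functions"):
        return source.value(pair)
    if m == "pair_scores":
        return neg_log_evalue(source, pair)
    raise ValueError(f"{spec.name}: unknown direct method {spec.method!r}")


def assemble_feature_matrix(
    catalog: Sequence[FeatureSpec],
    sources: Mapping[str, object],
    pairs: Sequence[GenePair],
) -> pd.DataFrame:
    """Compute every catalog feature for every pair.

    Returns a DataFrame indexed by (geneA, geneB) canonical tuples with
    one column per spec, in catalog order; missing values are NaN.
    Per-column coverage is logged; an all-missing column draws a
    warning.  Unresolvable source names raise ValueError.
    """
    names = [s.name for s in catalog]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in catalog")
    for spec in catalog:
        for src in spec.sources:
            if src not in sources:
                raise ValueError(f"{spec.name}: unknown source {src!r}")
        if spec.kind == "direct" and spec.method not in _DIRECT_METHODS:
            raise ValueError(f"{spec.name}: unknown direct method {spec.method!r}")

    index = pd.MultiIndex.from_tuples([(p.a, p.b) for p in pairs], names=["geneA", "geneB"])
    data: dict[str, list[float]] = {}
    for spec in catalog:
        col: list[float] = []
        if spec.kind == "direct":
            src = sources[spec.sources[0]]
            for p in pairs:
                v = _direct_value(spec, src, p)
                col.append(MISSING if v is None or (isinstance(v, float) and math.isnan(v)) else float(v))
        else:
            n1 = sources[spec.sources[0]]
            n2 = sources[spec.sources[1]]
            for p in pairs:
                v = overlay_value(n1, n2, p)
                col.append(MISSING if v is None else float(v))
        data[spec.name] = col
        coverage = 1.0 - float(np.mean(np.isnan(col))) if col else 0.0
        if col and coverage == 0.0:
            logger.warning("feature %s: all values missing", spec.name)
        else:
            logger.debug("feature %s: coverage %.1f%%", spec.name, 100 * coverage)
    return pd.DataFrame(data, index=index, columns=names, dtype=float)


# ---------------------------------------------------------------------------
# format helpers
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets into a gene -> set-of-group-ids map."""
    membership: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            group = parts[0]
            for gene in parts[2:]:
                if gene:
                    membership.setdefault(gene, set()).add(group)
    return membership


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df.set_index(["geneA", "geneB"])
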