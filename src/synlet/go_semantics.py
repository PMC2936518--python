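"""GO ontology handling and information-content based functional similarity.

Implements the standard information-content machinery over a Gene
Ontology DAG: per-term annotation probabilities estimated with ancestor
propagation, Lin's term-term semantic similarity through the minimum
subsumer (the common ancestor of lowest annotation probability), a
gene-pair functional similarity that averages Lin similarity over the
mutually-best-matching term pairs of the two genes' annotation sets,
and a whitelist-restricted shared-function count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import obonet
from Bio.UniProt import GOA

logger = logging.getLogger(__name__)

__all__ = [
    "Ontology",
    "AnnotationSet",
    "load_ontology",
    "load_annotations",
    "term_probabilities",
    "lin_similarity",
    "gene_functional_similarity",
    "shared_function_count",
]

# GAF single-letter aspect -> OBO namespace
ASPECT_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


class Ontology:
    """A GO-style term DAG (child -> parent links) with namespaces.

    Parent links are ``is_a`` and, by default, ``part_of``.  The graph
    must be acyclic; every term's ancestor closure is cached on demand.
    """

    def __init__(
        self,
        parents: Mapping[str, set[str]],
        namespace: Mapping[str, str],
    ) -> None:
        self.parents: dict[str, set[str]] = {t: set(p) for t, p in parents.items()}
        self.namespace: dict[str, str] = dict(namespace)
        for t, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise ValueError(f"parent {p!r} of {t!r} is not a term")
        self._check_acyclic()
        self._ancestors: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for t, ps in self.parents.items():
            g.add_edges_from((t, p) for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology parent graph contains a cycle")

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including the term itself."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        out = {term}
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        result = frozenset(out)
        self._ancestors[term] = result
        return result

    def common_ancestors(self, c1: str, c2: str) -> frozenset[str]:
        return self.ancestors(c1) & self.ancestors(c2)

    def roots(self) -> set[str]:
        return {t for t, ps in self.parents.items() if not ps}


@dataclass
class AnnotationSet:
    """Direct gene -> GO term annotations (pre-propagation)."""

    direct: dict[str, set[str]] = field(default_factory=dict)

    def add(self, gene: str, term: str) -> None:
        self.direct.setdefault(gene, set()).add(term)

    def genes(self) -> set[str]:
        return set(self.direct)

    def propagated(self, gene: str, ontology: Ontology) -> set[str]:
        """Annotation set closed under the ancestor relation."""
        out: set[str] = set()
        for t in self.direct.get(gene, ()):
            out |= ontology.ancestors(t)
        return out


def load_ontology(obo_path: str | Path, include_part_of: bool = True) -> Ontology:
    """Read an OBO 1.2 file into an :class:`Ontology`.

    Obsolete terms are excluded by obonet; ``is_a`` edges always count as
    parent links, ``part_of`` relationships optionally (on by default).
    """
    graph = obonet.read_obo(str(obo_path))
    parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
    namespace = {t: d.get("namespace", "biological_process") for t, d in graph.nodes(data=True)}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a" or (include_part_of and key == "part_of"):
            parents[child].add(parent)
    return Ontology(parents, namespace)


def load_annotations(gaf_path: str | Path, ontology: Ontology) -> AnnotationSet:
    """Read a GAF 2.x file, keeping annotations to known, non-NOT terms.

    Annotations to terms absent from the ontology are dropped (counted
    in a warning); rows with a NOT qualifier are excluded per GAF
    convention.
    """
    ann = AnnotationSet()
    n_unknown = 0
    with open(gaf_path) as fh:
        for rec in GOA.gafiterator(fh):
            if any(q.startswith("NOT") for q in rec["Qualifier"] if q):
                continue
            term = rec["GO_ID"]
            gene = rec["DB_Object_Symbol"] or rec["DB_Object_ID"]
            if term not in ontology:
                n_unknown += 1
                continue
            ann.add(gene, term)
    if n_unknown:
        logger.warning("%s: dropped %d annotation(s) to unknown terms", gaf_path, n_unknown)
    return ann


def term_probabilities(ontology: Ontology, annotations: AnnotationSet) -> dict[str, float]:
    """Per-term annotation probability p(c), estimated with propagation.

    Each gene's direct annotations are first closed under the ancestor
    relation; p(c) is the fraction of annotated genes (within c's
    namespace) whose propagated set contains c.  Terms never reached are
    omitted.  p is monotone non-decreasing child -> parent and equals 1
    at each namespace root among annotated genes.
    """
    if not annotations.direct:
        raise ValueError("no annotated genes")
    counts: dict[str, int] = {}
    ns_genes: dict[str, set[str]] = {}
    for gene in annotations.direct:
        prop = annotations.propagated(gene, ontology)
        for t in prop:
            counts[t] = counts.get(t, 0) + 1
            ns_genes.setdefault(ontology.namespace[t], set()).add(gene)
    probs: dict[str, float] = {}
    for t, c in counts.items():
        denom = len(ns_genes[ontology.namespace[t]])
        probs[t] = c / denom
    return probs


def minimum_subsumer(
    c1: str, c2: str, probs: Mapping[str, float], ontology: Ontology
) -> Optional[str]:
    """Common ancestor of c1, c2 with minimum annotation probability.

    Ancestor sets include the terms themselves, so if c1 subsumes c2 the
    minimum subsumer is c1.  Ties break by term id for determinism.
    Returns None when no common ancestor has a probability (disjoint
    sub-DAGs within a namespace).
    """
    common = [t for t in ontology.common_ancestors(c1, c2) if t in probs]
    if not common:
        return None
    return min(common, key=lambda t: (probs[t], t))


def lin_similarity(
    c1: str, c2: str, probs: Mapping[str, float], ontology: Ontology
) -> float:
    """Lin's semantic similarity: 2 ln p(ms) / (ln p(c1) + ln p(c2)).

    ``ms`` is the minimum subsumer.  Identical terms score 1 (even at
    p < 1); when both terms sit at p = 1 the denominator vanishes and
    the similarity is defined as 0 (no information content to share).
    """
    for c in (c1, c2):
        if c not in probs:
            raise ValueError(f"term {c!r} has no annotation probability")
    if ontology.namespace[c1] != ontology.namespace[c2]:
        raise ValueError(
            f"terms {c1!r} and {c2!r} are in different namespaces"
        )
    if c1 == c2:
        return 1.0 if probs[c1] < 1.0 else 0.0
    denom = math.log(probs[c1]) + math.log(probs[c2])
    if denom == 0.0:
        return 0.0
    ms = minimum_subsumer(c1, c2, probs, ontology)
    if ms is None:
        return 0.0
    return 2.0 * math.log(probs[ms]) / denom


def gene_functional_similarity(
    terms_a: Iterable[str],
    terms_b: Iterable[str],
    probs: Mapping[str, float],
    ontology: Ontology,
) -> Optional[float]:
    """Mutual-best-match functional similarity of two annotation sets.

    For each term in A the best Lin match in B is found and vice versa;
    the similarity is the mean Lin value over the mutually-best pairs
    (x, y) where x's best is y and y's best is x.  Best-match ties break
    toward the higher Lin value, then the lexicographically smaller term
    id.  Returns None (a missing value, not zero) when either set is
    empty after restriction to terms with probabilities.
    """
    a = sorted({t for t in terms_a if t in probs})
    b = sorted({t for t in terms_b if t in probs})
    if not a or not b:
        return None

    sim_cache: dict[tuple[str, str], float] = {}

    def sim(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        val = sim_cache.get(key)
        if val is None:
            val = lin_similarity(key[0], key[1], probs, ontology)
            sim_cache[key] = val
        return val

    def best(x: str, candidates: list[str]) -> str:
        # max Lin; ties go to the lexicographically smallest term id
        # (candidates are sorted, strict improvement keeps the first)
        winner, winner_sim = candidates[0], sim(x, candidates[0])
        for y in candidates[1:]:
            s = sim(x, y)
            if s > winner_sim:
                winner, winner_sim = y, s
        return winner

    best_a = {x: best(x, b) for x in a}
    best_b = {y: best(y, a) for y in b}
    mutual = [(x, y) for x, y in best_a.items() if best_b[y] == x]
    if not mutual:
        # cannot happen: the globally best pair is always mutual
        return None  # pragma: no cover
    return sum(sim(x, y) for x, y in mutual) / len(mutual)


def shared_function_count(
    gene_a: str,
    gene_b: str,
    annotations: AnnotationSet,
    ontology: Ontology,
    whitelist: set[str],
) -> int:
    """Number of whitelisted terms in both genes' propagated sets.

    The whitelist restricts the count to a curated set of informative
    terms, guarding against inflation by near-universal general classes.
    Unannotated genes simply contribute 0.
    """
    pa = annotations.propagated(gene_a, ontology)
    pb = annotations.propagated(gene_b, ontology)
    return len(pa & pb & whitelist)


def read_term_whitelist(path: str | Path) -> set[str]:
    """One term id per line; '#' comments and blanks skipped."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split()[0])
    return out
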