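"""Weighted, undirected gene-pair networks.

A network here is a named collection of weighted edges between genes,
stored under canonical (lexicographically ordered) pair keys so that
lookups are orientation-free.  An absent edge is *missing information*,
never weight zero: downstream feature computations propagate absence as
a missing feature value rather than conflating it with "no association".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "GenePair",
    "WeightedNetwork",
    "SparsifySpec",
    "read_edge_list",
    "write_edge_list",
    "sparsify",
    "pair_connectivity",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in canonical (sorted) order.

    Raises ValueError for self-pairs: a gene cannot be synthetic lethal
    with itself, and networks carry no self-loops.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: ({a!r}, {b!r})")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True, order=True)
class GenePair:
    """An unordered pair of distinct gene identifiers.

    (a, b) and (b, a) construct the same object; ``a`` is always the
    lexicographically smaller identifier.
    """

    a: str
    b: str

    def __init__(self, a: str, b: str) -> None:
        a, b = canonical_pair(a, b)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    def __iter__(self) -> Iterator[str]:
        return iter((self.a, self.b))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.a}--{self.b}"


class WeightedNetwork:
    """Symmetric weighted network over opaque gene identifiers.

    Edges are stored in a dict keyed by canonical pairs; an adjacency
    map is maintained alongside for neighbourhood queries (degree,
    transitive overlays).  ``get`` returns ``None`` for a missing edge.
    """

    def __init__(self, name: str = "", edges: Optional[dict] = None) -> None:
        self.name = name
        self._edges: dict[tuple[str, str], float] = {}
        self._adj: dict[str, dict[str, float]] = {}
        if edges:
            for (a, b), w in edges.items():
                self.add_edge(a, b, w)

    # -- construction -------------------------------------------------
    def add_edge(self, a: str, b: str, weight: float) -> None:
        key = canonical_pair(a, b)
        self._edges[key] = float(weight)
        self._adj.setdefault(key[0], {})[key[1]] = float(weight)
        self._adj.setdefault(key[1], {})[key[0]] = float(weight)

    # -- queries ------------------------------------------------------
    def get(self, a: str, b: str) -> Optional[float]:
        """Edge weight, or None if the edge is absent."""
        if a == b:
            return None
        return self._edges.get(canonical_pair(a, b))

    def has_edge(self, a: str, b: str) -> bool:
        return a != b and canonical_pair(a, b) in self._edges

    def neighbors(self, gene: str) -> dict[str, float]:
        """Map neighbour -> edge weight (empty for absent genes)."""
        return self._adj.get(gene, {})

    def degree(self, gene: str) -> int:
        """Number of incident edges; 0 for genes absent from the network."""
        return len(self._adj.get(gene, {}))

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for (a, b), w in self._edges.items():
            yield a, b, w

    def __len__(self) -> int:
        return len(self._edges)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"WeightedNetwork(name={self.name!r}, "
            f"nodes={len(self._adj)}, edges={len(self._edges)})"
        )


@dataclass
class SparsifySpec:
    """Edge-retention thresholds.

    Retain an edge iff its weight is strictly above ``positive_threshold``
    or (when given) strictly below ``negative_threshold``.  At least one
    threshold must be present.
    """

    positive_threshold: Optional[float] = None
    negative_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.positive_threshold is None and self.negative_threshold is None:
            raise ValueError("at least one threshold must be given")
        if (
            self.positive_threshold is not None
            and self.negative_threshold is not None
            and self.negative_threshold > self.positive_threshold
        ):
            raise ValueError("negative_threshold must be <= positive_threshold")

    def keeps(self, w: float) -> bool:
        if self.positive_threshold is not None and w > self.positive_threshold:
            return True
        if self.negative_threshold is not None and w < self.negative_threshold:
            return True
        return False


def sparsify(net: WeightedNetwork, spec: SparsifySpec) -> WeightedNetwork:
    """Drop all edges not passing the thresholds (idempotent)."""
    out = WeightedNetwork(name=net.name)
    for a, b, w in net.edges():
        if spec.keeps(w):
            out.add_edge(a, b, w)
    if out.n_edges == 0:
        logger.warning("sparsify(%s): no edges retained", net.name)
    return out


def pair_connectivity(sl_net: WeightedNetwork, pair: GenePair) -> int:
    """min(degree(a), degree(b)) in the given network.

    Used to identify the least-connected known-SL pairs, for which
    SL-dependent features are weakest.
    """
    return min(sl_net.degree(pair.a), sl_net.degree(pair.b))


def read_edge_list(path: str | Path, name: str = "") -> WeightedNetwork:
    """Read a TSV edge list (geneA, geneB, weight; '#' comments skipped).

    Duplicate entries for the same unordered pair are resolved by keeping
    the weight of maximum absolute value; self-loops are dropped with a
    warning.  Non-numeric weights raise ValueError naming the line.
    """
    path = Path(path)
    net = WeightedNetwork(name=name or path.stem)
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw_w = parts[0], parts[1], parts[2]
            try:
                w = float(raw_w)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric weight {raw_w!r}") from exc
            if not math.isfinite(w):
                raise ValueError(f"{path}:{lineno}: non-finite weight {raw_w!r}")
            if a == b:
                n_self += 1
                continue
            prev = net.get(a, b)
            if prev is None or abs(w) > abs(prev):
                net.add_edge(a, b, w)
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    return net


def write_edge_list(net: WeightedNetwork, path: str | Path) -> None:
    """Write a network as a canonical-order TSV edge list."""
    with open(path, "w") as fh:
        fh.write(f"# network: {net.name}\n")
        for (a, b), w in sorted(net._edges.items()):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def network_from_pairs(pairs: Iterable[GenePair], name: str = "SL", weight: float = 1.0) -> WeightedNetwork:
    """Build an unweighted (all edges = ``weight``) network from gene pairs.

    This is how the known-SL interaction network is materialised from a
    list of positive examples, e.g. per training fold inside
    cross-validation.
    """
    net = WeightedNetwork(name=name)
    for p in pairs:
        net.add_edge(p.a, p.b, weight)
    return net
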