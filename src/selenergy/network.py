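"""Score-weighted logratio networks and their spanning-tree reduction.

A logratio network is a directed graph over taxa where each edge points from
the numerator to the denominator of a ratio and carries that ratio's score.
Graph algorithms run on the undirected projection; direction is metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .compositional import LogratioFrame, ratio_name
from .dcv import DCVScores

__all__ = [
    "LogratioNetwork",
    "SpanningTreeSignature",
    "covering_prefix_network",
    "maximum_spanning_tree",
    "subframe",
    "global_clustering_coefficient",
]


@dataclass
class LogratioNetwork:
    """Taxa vertices with one weighted (numerator -> denominator) edge per ratio."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        seen = set()
        for num, den, w in self.edges:
            if num == den:
                raise ValueError(f"self-loop on {num!r}")
            key = frozenset((num, den))
            if key in seen:
                raise ValueError(f"duplicate edge between {num!r} and {den!r}")
            seen.add(key)
            if not np.isfinite(w):
                raise ValueError("non-finite edge weight")

    @property
    def q(self) -> int:
        return len(self.edges)

    def to_undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g


@dataclass
class SpanningTreeSignature:
    """An acyclic, ordered set of ratio edges (a forest over the taxa)."""

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        if not self.edges:
            return
        g = nx.Graph((num, den) for num, den, _ in self.edges)
        if g.number_of_edges() != len(self.edges) or not nx.is_forest(g):
            raise ValueError("signature edges must form a forest")

    @property
    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for num, den, _ in self.edges:
            seen.setdefault(num)
            seen.setdefault(den)
        return list(seen)

    @property
    def ratio_names(self) -> list[str]:
        return [ratio_name(num, den) for num, den, _ in self.edges]

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def covering_prefix_network(scores: DCVScores,
                            ratios: list[tuple[str, str]] | None = None) -> LogratioNetwork:
    """Shortest score-descending prefix of ratios covering all taxa, extended
    (still in score order) until the covered graph is a single component.

    ``ratios`` supplies the (numerator, denominator) pairs aligned with the
    scores; when omitted they are recovered by splitting the ratio names.
    """
    if ratios is None:
        ratios = [tuple(nm.split("/", 1)) for nm in scores.ratio_names]  # type: ignore
    if len(ratios) != len(scores.scores):
        raise ValueError("ratios and scores length mismatch")
    taxa: dict[str, None] = {}
    for num, den in ratios:
        taxa.setdefault(num)
        taxa.setdefault(den)
    d = len(taxa)
    names = scores.ratio_names
    order = sorted(range(len(names)), key=lambda i: (-scores.scores[i], names[i]))

    uf = _UnionFind(taxa)
    covered: set[str] = set()
    n_components = d
    edges: list[tuple[str, str, float]] = []
    for i in order:
        num, den = ratios[i]
        edges.append((num, den, float(scores.scores[i])))
        covered.add(num)
        covered.add(den)
        if uf.union(num, den):
            n_components -= 1
        if len(covered) == d and n_components == 1:
            break
    else:
        raise ValueError("supplied ratios do not connect all taxa")
    return LogratioNetwork(list(taxa), edges)


def maximum_spanning_tree(G: LogratioNetwork) -> SpanningTreeSignature:
    """Maximum-weight spanning tree of the undirected projection.

    Kruskal's greedy scan over edges sorted by (descending weight, ratio
    name) — deterministic under ties and weight-optimal.
    """
    und = G.to_undirected()
    if und.number_of_nodes() > 0 and not nx.is_connected(und):
        raise ValueError("network must be connected to extract a spanning tree")
    d = len(G.nodes)
    ranked = sorted(G.edges, key=lambda e: (-e[2], ratio_name(e[0], e[1])))
    uf = _UnionFind(G.nodes)
    chosen: list[tuple[str, str, float]] = []
    for num, den, w in ranked:
        if uf.union(num, den):
            chosen.append((num, den, w))
            if len(chosen) == d - 1:
                break
    return SpanningTreeSignature(chosen)


def subframe(Z: LogratioFrame, sig: SpanningTreeSignature) -> LogratioFrame:
    """Columns of ``Z`` matching the signature's edges, in signature order.

    If an edge is stored with the opposite orientation to the frame's column,
    the column is negated and relabeled so values always equal
    ``log(numerator/denominator)`` of the returned ratio labels.
    """
    index = {pair: i for i, pair in enumerate(Z.ratios)}
    cols = []
    ratios = []
    signs = []
    for num, den, _ in sig.edges:
        if (num, den) in index:
            cols.append(index[(num, den)])
            signs.append(1.0)
            ratios.append((num, den))
        elif (den, num) in index:
            cols.append(index[(den, num)])
            signs.append(-1.0)
            ratios.append((num, den))
        else:
            raise KeyError(f"ratio {num}/{den} not present in frame")
    if not cols:
        return LogratioFrame(np.empty((Z.n_samples, 0)), [], Z.sample_ids)
    values = Z.values[:, cols] * np.asarray(signs)
    return LogratioFrame(values, ratios, Z.sample_ids)


def global_clustering_coefficient(obj: LogratioNetwork | SpanningTreeSignature) -> float:
    """Transitivity: 3 * triangles / connected triples (0 when no triples)."""
    if isinstance(obj, SpanningTreeSignature):
        g = nx.Graph((num, den) for num, den, _ in obj.edges)
    else:
        g = obj.to_undirected()
    if g.number_of_edges() == 0:
        return 0.0
    return float(nx.transitivity(g))
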