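"""Partition and dismantling diagnostics.

Implements the three partition-quality criteria used to benchmark divisive
community detection — normalized mutual information (NMI), Newman modularity
Q, and partition density D — together with two edge-percolation diagnostics:
the relative size of the giant component (RGC) and the normalized
susceptibility S̃, tracked along a centrality-ordered edge-removal curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import networkx as nx

from .graphcore import EdgeKey, Partition, canonical_edge

__all__ = [
    "nmi",
    "modularity",
    "partition_density",
    "community_diameter",
    "normalized_susceptibility",
    "DismantlePoint",
    "dismantle_curve",
]


def _confusion(p1: Partition, p2: Partition) -> list[list[int]]:
    a = [[0] * p2.k for _ in range(p1.k)]
    for v in p1.vertices:
        a[p1[v] - 1][p2[v] - 1] += 1
    return a


def nmi(p1: Partition, p2: Partition) -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    Computed from the confusion matrix A (A_ij = vertices in community i of
    p1 and community j of p2) as

        I = -2 ΣΣ A_ij log(A_ij N / A_i. A_.j)
            / [Σ A_i. log(A_i./N) + Σ A_.j log(A_.j/N)]

    with the 0 log 0 = 0 convention.  When both partitions are the trivial
    single community the denominator vanishes; the partitions are then
    identical and the value is 1 by convention.
    """
    if p1.vertices != p2.vertices:
        raise ValueError("partitions cover different vertex sets")
    n = len(p1)
    a = _confusion(p1, p2)
    row = [sum(r) for r in a]
    col = [sum(a[i][j] for i in range(p1.k)) for j in range(p2.k)]
    denom = sum(r * math.log(r / n) for r in row if r) + sum(
        c * math.log(c / n) for c in col if c
    )
    if denom == 0.0:
        return 1.0
    num = -2.0 * sum(
        a[i][j] * math.log(a[i][j] * n / (row[i] * col[j]))
        for i in range(p1.k)
        for j in range(p2.k)
        if a[i][j]
    )
    return num / denom


def modularity(g: nx.Graph, p: Partition) -> float:
    """Newman modularity Q = Σ_c [ l_c/M - (d_c/2M)^2 ].

    l_c is the number of edges with both endpoints in community c and d_c
    the total degree of the community's vertices.
    """
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    if not p.vertices >= set(g.nodes):
        raise ValueError("partition does not cover the graph's vertices")
    q = 0.0
    for comm in p.communities():
        l_c = g.subgraph(comm).number_of_edges()
        d_c = sum(d for _, d in g.degree(comm))
        q += l_c / m - (d_c / (2 * m)) ** 2
    return q


def partition_density(g: nx.Graph, p: Partition) -> float:
    """Partition density D = (2/M) Σ_c m_c [m_c - (n_c - 1)] / [(n_c - 2)(n_c - 1)].

    m_c and n_c are the edge and vertex counts of community c; communities
    with n_c <= 2 contribute 0 (the limit convention — the formula is
    indeterminate there).  D is 0 when every community is a tree and 1 when
    the communities are edge-covering cliques on >= 3 vertices.
    """
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("partition density is undefined on an edgeless graph")
    if not p.vertices >= set(g.nodes):
        raise ValueError("partition does not cover the graph's vertices")
    total = 0.0
    for comm in p.communities():
        n_c = len(comm)
        if n_c <= 2:
            continue
        m_c = g.subgraph(comm).number_of_edges()
        total += m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1))
    return 2.0 * total / m


def community_diameter(g_original: nx.Graph, community: Iterable[str]) -> float:
    """Diameter of the subgraph of the original graph induced on *community*.

    Returns ``math.inf`` when the induced subgraph is disconnected and 0 for
    a singleton.
    """
    community = set(community)
    if not community:
        raise ValueError("community is empty")
    sub = g_original.subgraph(community)
    if len(community) == 1:
        return 0
    if not nx.is_connected(sub):
        return math.inf
    return nx.diameter(sub)


def normalized_susceptibility(component_sizes: Iterable[int], n: int) -> float:
    """S̃ = Σ_s n_s s² / N over all components except one largest.

    When several components tie for the maximum size exactly one instance is
    excluded.  Zero while the graph is connected; peaks where the network
    disintegrates along a removal curve.
    """
    sizes = sorted(component_sizes)
    if sum(sizes) != n:
        raise ValueError(f"component sizes sum to {sum(sizes)}, expected N={n}")
    if not sizes:
        raise ValueError("no components")
    sizes.pop()  # exclude exactly one maximal component
    return sum(s * s for s in sizes) / n


@dataclass(frozen=True)
class DismantlePoint:
    """State of the graph after removing a fraction *f* of the edges."""

    f: Fraction
    rgc: float
    s_tilde: float


def _component_state(h: nx.Graph, n: int, removed: int, m: int) -> DismantlePoint:
    sizes = [len(c) for c in nx.connected_components(h)]
    return DismantlePoint(
        f=Fraction(removed, m),
        rgc=max(sizes) / n,
        s_tilde=normalized_susceptibility(sizes, n),
    )


def dismantle_curve(
    g: nx.Graph, kind: str = "antitriangle", recompute: bool = False
) -> list[DismantlePoint]:
    """Remove all edges in centrality order, tracking (f, RGC, S̃) after each.

    ``kind`` is one of ``antitriangle``, ``betweenness`` (both removed
    highest-first) or ``clustering_coefficient`` (removed lowest-first,
    matching its divisive use).  With ``recompute`` the scores are refreshed
    after every removal; otherwise the static scores of the intact graph fix
    the whole removal order.  The first point is the intact graph at f = 0;
    the last has all M edges removed.
    """
    from .baselines import centrality_scores, removes_max

    m = g.number_of_edges()
    n = g.number_of_nodes()
    if m == 0 or n == 0:
        raise ValueError("dismantling needs a non-empty graph")
    h = g.copy()
    curve = [_component_state(h, n, 0, m)]
    maximize = removes_max(kind)

    def _next_edge() -> EdgeKey:
        scores = _next_edge.scores
        if maximize:
            best = max(scores.values())
        else:
            best = min(scores.values())
        return min(e for e, s in scores.items() if s == best)

    _next_edge.scores = centrality_scores(h, kind)
    removed = 0
    while h.number_of_edges() > 0:
        e = _next_edge()
        h.remove_edge(*e)
        removed += 1
        if recompute:
            if h.number_of_edges():
                _next_edge.scores = centrality_scores(h, kind)
            else:
                _next_edge.scores = {}
        else:
            del _next_edge.scores[e]
        curve.append(_component_state(h, n, removed, m))
    return curve
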