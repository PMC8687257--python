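"""Comparison edge centralities and a generic divisive detector.

Covers the two classical edge centralities the antitriangle score is
benchmarked against — shortest-path edge betweenness (the Girvan–Newman
score) and the Radicchi edge clustering coefficient — plus a divisive
detector that removes edges to exhaustion and returns the partition
maximizing a chosen global objective (modularity Q or partition density D)
over the whole removal history.
"""

from __future__ import annotations

from fractions import Fraction

import networkx as nx

from .antitriangle import score_all_edges
from .graphcore import EdgeKey, Partition, canonical_edge

__all__ = [
    "CENTRALITY_KINDS",
    "edge_betweenness_scores",
    "edge_clustering_scores",
    "centrality_scores",
    "removes_max",
    "divisive_detect",
]

CENTRALITY_KINDS = ("antitriangle", "betweenness", "clustering_coefficient")


def edge_betweenness_scores(g: nx.Graph) -> dict[EdgeKey, float]:
    """Shortest-path edge betweenness, as raw per-pair counts.

    Tied shortest paths share credit fractionally (Brandes accumulation);
    the values are unnormalized, which leaves any Pearson correlation and
    any removal order unchanged.
    """
    raw = nx.edge_betweenness_centrality(g, normalized=False)
    return {canonical_edge(u, v): s for (u, v), s in raw.items()}


def edge_clustering_scores(
    g: nx.Graph, plus_one: bool = True
) -> dict[EdgeKey, Fraction]:
    """Edge clustering coefficient: triangles through the edge over the
    maximum possible.

    With ``plus_one`` (the default, the degeneracy-avoiding Radicchi form)
    the score is (z_ij + 1) / min(k_i - 1, k_j - 1), otherwise the plain
    ratio z_ij / min(k_i - 1, k_j - 1).  When min(k_i - 1, k_j - 1) = 0 the
    denominator is clamped to 1 (z is necessarily 0 there).
    """
    out: dict[EdgeKey, Fraction] = {}
    for u, v in g.edges():
        z = sum(1 for w in g[u] if w in g[v])
        denom = max(min(g.degree(u) - 1, g.degree(v) - 1), 1)
        out[canonical_edge(u, v)] = Fraction(z + (1 if plus_one else 0), denom)
    return out


def centrality_scores(g: nx.Graph, kind: str, **kwargs) -> dict[EdgeKey, object]:
    """Dispatch to one of the three edge centralities by name.

    ``kwargs`` are forwarded to the selected scorer (``adjusted`` for the
    antitriangle centrality, ``plus_one`` for the clustering coefficient).
    """
    if kind == "antitriangle":
        return score_all_edges(g, **kwargs)
    if kind == "betweenness":
        return edge_betweenness_scores(g)
    if kind == "clustering_coefficient":
        return edge_clustering_scores(g, **kwargs)
    raise ValueError(f"unknown centrality kind {kind!r}; expected {CENTRALITY_KINDS}")


def removes_max(kind: str) -> bool:
    """Whether divisive removal deletes the *highest*-scoring edge for *kind*.

    Betweenness and antitriangle single out inter-community edges with high
    scores; the clustering coefficient marks them with low scores.
    """
    if kind not in CENTRALITY_KINDS:
        raise ValueError(f"unknown centrality kind {kind!r}")
    return kind != "clustering_coefficient"


def divisive_detect(
    g: nx.Graph,
    kind: str = "betweenness",
    objective: str = "Q",
    plus_one: bool = True,
) -> tuple[Partition, float]:
    """Full divisive detection: remove edges to exhaustion, keep the best cut.

    Removes one edge per iteration (highest betweenness/antitriangle score,
    or lowest clustering coefficient), recomputing the scores on the current
    graph each step, until no edge remains — the M+1 component partitions
    encountered along the way are evaluated with the chosen objective
    (modularity ``Q`` or partition density ``D``, always against the
    *original* graph) and the argmax is returned together with its value.

    ``kind='betweenness'`` reproduces Girvan–Newman; the clustering
    coefficient variants are the ECCA baselines.
    """
    from .metrics import modularity, partition_density

    if objective == "Q":
        score_partition = lambda p: modularity(g, p)
    elif objective == "D":
        score_partition = lambda p: partition_density(g, p)
    else:
        raise ValueError(f"objective must be 'Q' or 'D', got {objective!r}")

    kwargs = {"plus_one": plus_one} if kind == "clustering_coefficient" else {}
    maximize = removes_max(kind)
    h = g.copy()
    if h.number_of_edges() == 0:
        # nothing to remove and the objectives are undefined: all singletons
        return Partition.from_communities({v} for v in h), float("nan")

    def _current_partition() -> Partition:
        return Partition.from_communities(nx.connected_components(h))

    best_p = _current_partition()
    best_val = score_partition(best_p)
    while h.number_of_edges() > 0:
        scores = centrality_scores(h, kind, **kwargs)
        target = max(scores.values()) if maximize else min(scores.values())
        edge = min(e for e, s in scores.items() if s == target)
        h.remove_edge(*edge)
        p = _current_partition()
        val = score_partition(p)
        if val > best_val:
            best_p, best_val = p, val
    return best_p, best_val
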