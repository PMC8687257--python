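"""Edge antitriangle centrality: exact P4 / potential-P4 counting per edge.

An induced **P4** is a path on four distinct vertices with its three path
edges present and all three chords absent.  A **potential P4** through an
edge is a length-3 non-backtracking walk: four positions, three consecutive
edges, where repeats of the first/last vertex and chords are allowed.  Both
quantities are attributed to an edge by the position it occupies in the path
or walk — left (first edge, the lower canonical endpoint terminal), central
(middle edge), or right (first edge with the upper canonical endpoint
terminal).

For an edge e = (i, j) with canonical key order i < j the positional
potential counts have closed forms in the vertex degrees:

* central: (k_i - 1)(k_j - 1) ordered choices of a neighbour on each side
  (coincidence a = b and chords allowed);
* left:  sum over l in N(j)\\{i} of (k_l - 1), the walks i-j-l-m;
* right: sum over l in N(i)\\{j} of (k_l - 1), the walks j-i-l-m.

The antitriangle centrality is PN / (PPN + 1): the induced-P4 count over the
potential count, with the +1 keeping the ratio finite on degenerate edges.
Intra-community edges sit in many triangles, hence many potential but few
induced P4s (a chord kills an induced P4) and a low score; inter-community
edges score high.  The score is an exact :class:`fractions.Fraction` so that
ties in the divisive removal loop are detected exactly.
"""

from __future__ import annotations

from fractions import Fraction
from typing import NamedTuple

import networkx as nx

from .graphcore import EdgeKey, canonical_edge, edge_keys

__all__ = [
    "PositionCounts",
    "MissingEdgeError",
    "potential_p4_counts",
    "p4_counts",
    "antitriangle_score",
    "score_all_edges",
    "brute_force_p4_census",
    "affected_edges",
]


class MissingEdgeError(KeyError):
    """The requested edge is not present in the graph."""


class PositionCounts(NamedTuple):
    """Per-position counts for one edge: left / central / right."""

    left: int
    central: int
    right: int

    @property
    def total(self) -> int:
        return self.left + self.central + self.right


def _require_edge(g: nx.Graph, e: EdgeKey) -> EdgeKey:
    i, j = canonical_edge(*e)
    if not g.has_edge(i, j):
        raise MissingEdgeError(f"edge {(i, j)!r} not in graph")
    return i, j


def potential_p4_counts(g: nx.Graph, e: EdgeKey) -> PositionCounts:
    """Count potential P4s (non-backtracking length-3 walks) through edge *e*.

    Walk repeats of the terminal vertices and chords are allowed; only
    immediate backtracking is excluded.  These are the degree closed forms
    above, evaluated exactly.
    """
    i, j = _require_edge(g, e)
    ki = g.degree(i)
    kj = g.degree(j)
    central = (ki - 1) * (kj - 1)
    left = sum(g.degree(l) - 1 for l in g[j] if l != i)
    right = sum(g.degree(l) - 1 for l in g[i] if l != j)
    return PositionCounts(left=left, central=central, right=right)


def p4_counts(g: nx.Graph, e: EdgeKey) -> PositionCounts:
    """Count induced P4s containing edge *e*, attributed by position.

    Each undirected induced P4 contributes exactly 1 to exactly one
    positional bucket of each of its three edges: central if *e* is the
    middle edge, left/right if the lower/upper canonical endpoint of *e* is
    the terminal vertex of the path.
    """
    i, j = _require_edge(g, e)
    ni = set(g[i])
    nj = set(g[j])

    central = 0
    for a in ni:
        if a == j or a in nj:
            continue
        na = g[a]
        for b in nj:
            # induced a-i-j-b: distinct vertices, chords a-j, i-b, a-b absent
            if b == i or b == a or b in ni or b in na:
                continue
            central += 1

    def _terminal(first: str, second: str, n_first: set, n_second: set) -> int:
        # induced paths first-second-l-m with `first` the terminal vertex
        count = 0
        for l in n_second:
            if l == first or l in n_first:
                continue
            for m in g[l]:
                if m == first or m == second or m in n_first or m in n_second:
                    continue
                count += 1
        return count

    left = _terminal(i, j, ni, nj)
    right = _terminal(j, i, nj, ni)
    return PositionCounts(left=left, central=central, right=right)


def antitriangle_score(g: nx.Graph, e: EdgeKey, adjusted: bool = True) -> Fraction:
    """Antitriangle centrality of edge *e*, as an exact rational.

    With ``adjusted`` (the default, used throughout the divisive detector)
    the score is the degeneracy-free PN / (PPN + 1); with ``adjusted=False``
    it is the raw ratio PN / PPN (0 when PPN is 0), the form under which the
    published centrality correlations were computed.
    """
    ppn = potential_p4_counts(g, e).total
    pn = p4_counts(g, e).total
    if adjusted:
        return Fraction(pn, ppn + 1)
    return Fraction(pn, ppn) if ppn else Fraction(0)


def score_all_edges(g: nx.Graph, adjusted: bool = True) -> dict[EdgeKey, Fraction]:
    """Antitriangle scores for every edge, keyed by canonical edge key."""
    return {e: antitriangle_score(g, e, adjusted=adjusted) for e in edge_keys(g)}


def brute_force_p4_census(
    g: nx.Graph, max_vertices: int = 60
) -> tuple[dict[EdgeKey, PositionCounts], dict[EdgeKey, PositionCounts]]:
    """Independent oracle: per-edge (PN, PPN) position counts by enumeration.

    Potential P4s are enumerated as all directed non-backtracking length-3
    walks; induced P4s as all directed induced 4-paths.  A directed walk
    v0-v1-v2-v3 is attributed to the bucket of its *first* edge determined by
    which canonical endpoint v0 is, and to the central bucket of its middle
    edge only in the canonical i->j direction, so each undirected object is
    counted once per positional bucket.  Deliberately independent of the
    closed-form path used by :func:`potential_p4_counts` / :func:`p4_counts`.
    """
    n = g.number_of_nodes()
    if n > max_vertices:
        raise ValueError(f"brute-force census guarded to N <= {max_vertices}, got {n}")

    pn = {e: [0, 0, 0] for e in edge_keys(g)}   # [left, central, right]
    ppn = {e: [0, 0, 0] for e in edge_keys(g)}

    def _attribute(table, v0, v1, v2, v3):
        first = canonical_edge(v0, v1)
        table[first][0 if v0 == first[0] else 2] += 1
        mid = canonical_edge(v1, v2)
        if (v1, v2) == mid:  # count the middle edge in one direction only
            table[mid][1] += 1

    for v0 in g:
        for v1 in g[v0]:
            for v2 in g[v1]:
                if v2 == v0:
                    continue
                for v3 in g[v2]:
                    if v3 == v1:
                        continue
                    _attribute(ppn, v0, v1, v2, v3)
                    if (
                        v3 != v0
                        and not g.has_edge(v0, v2)
                        and not g.has_edge(v0, v3)
                        and not g.has_edge(v1, v3)
                    ):
                        _attribute(pn, v0, v1, v2, v3)

    to_counts = lambda table: {e: PositionCounts(*c) for e, c in table.items()}
    return to_counts(pn), to_counts(ppn)


def affected_edges(g: nx.Graph, removed: EdgeKey) -> set[EdgeKey]:
    """Edges whose score can change when *removed* is deleted.

    With ``removed = (i, j)`` still present in *g*, these are the surviving
    edges with at least one endpoint in N(i) ∪ N(j); only their counts
    involve the degrees or the adjacency of i and j.  Rescoring exactly this
    set after the deletion reproduces a full rescore of the residual graph.
    """
    i, j = _require_edge(g, removed)
    hood = set(g[i]) | set(g[j])  # contains i and j themselves
    out: set[EdgeKey] = set()
    for v in hood:
        for u in g[v]:
            e = canonical_edge(u, v)
            if e != (i, j) and e != (j, i):
                out.add(e)
    out.discard(canonical_edge(i, j))
    return out
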