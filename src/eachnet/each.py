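"""The EACH divisive detector: removal loop plus isolated-vertex handling.

EACH scores every edge with the antitriangle centrality, repeatedly removes
the highest-scoring edge (rescoring only the edges a removal can affect),
and stops as soon as every remaining edge scores zero — i.e. when every
residual component is P4-free.  Connected cographs have diameter at most 2,
which is what makes the final communities compact.  Vertices isolated by
the removals are then re-attached to the non-trivial component they share
the largest fraction of neighbours with; skipping that last step yields the
EAC variant, where isolated vertices stay as singleton communities.

Ties are resolved deterministically: among equally maximal scores the
canonically smallest edge key is removed, so a run is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import networkx as nx

from .antitriangle import affected_edges, antitriangle_score, score_all_edges
from .graphcore import EdgeKey, Partition, canonical_edge

__all__ = [
    "RemovalEvent",
    "EACHResult",
    "removal_loop",
    "component_partition",
    "vertex_component_closeness",
    "attach_isolated",
    "run_each",
]


@dataclass(frozen=True)
class RemovalEvent:
    """One iteration of the removal loop (1-based step index)."""

    step: int
    edge: EdgeKey
    score_at_removal: Fraction


@dataclass(frozen=True)
class EACHResult:
    """Full outcome of a detection run."""

    removals: tuple[RemovalEvent, ...]
    residual_components: tuple[frozenset[str], ...]
    partition: Partition
    rr: Fraction          #: edge removal ratio |removals| / M
    noc: int              #: number of obtained communities, == partition.k

    @property
    def iterations(self) -> int:
        return len(self.removals)


def removal_loop(g: nx.Graph) -> tuple[nx.Graph, tuple[RemovalEvent, ...]]:
    """Delete the maximal-score edge until every remaining score is zero.

    Returns the residual graph (all vertices retained) and the removal
    sequence.  After each deletion only the edges with an endpoint in the
    deleted edge's joint neighbourhood are rescored; this is exact, and is
    what keeps the loop near-linear on sparse graphs.
    """
    h = g.copy()
    scores = score_all_edges(h)
    removals: list[RemovalEvent] = []
    step = 0
    while scores:
        top = max(scores.values())
        if top == 0:
            break
        edge = min(e for e, s in scores.items() if s == top)
        step += 1
        removals.append(RemovalEvent(step=step, edge=edge, score_at_removal=top))
        touched = affected_edges(h, edge)
        h.remove_edge(*edge)
        del scores[edge]
        for e in touched:
            scores[e] = antitriangle_score(h, e)
    return h, tuple(removals)


def component_partition(
    residual: nx.Graph,
) -> tuple[list[frozenset[str]], set[str]]:
    """Split residual components into non-trivial ones (>= 2 vertices) and
    isolated vertices (singleton components)."""
    nontrivial: list[frozenset[str]] = []
    isolated: set[str] = set()
    for comp in nx.connected_components(residual):
        if len(comp) >= 2:
            nontrivial.append(frozenset(comp))
        else:
            isolated.update(comp)
    nontrivial.sort(key=min)
    return nontrivial, isolated


def vertex_component_closeness(
    v: str, nc: Iterable[str], g_original: nx.Graph
) -> Fraction:
    """Closeness |N_v ∩ V_NC| / |V_NC| of isolated vertex *v* to component *nc*.

    The neighbourhood is taken in the *original* graph, before any removals.
    """
    nc = frozenset(nc)
    if not nc:
        raise ZeroDivisionError("closeness to an empty component is undefined")
    if v in nc:
        raise ValueError(f"vertex {v!r} already belongs to the component")
    shared = sum(1 for u in g_original[v] if u in nc)
    return Fraction(shared, len(nc))


def attach_isolated(
    nontrivial: Sequence[frozenset[str]],
    isolated: Iterable[str],
    g_original: nx.Graph,
) -> Partition:
    """Re-attach isolated vertices to their closest non-trivial component.

    All assignments are decided simultaneously against the pre-attachment
    component list.  A vertex joins the component maximizing the closeness
    ratio, provided that maximum is strictly positive; closeness ties go to
    the component with more shared neighbours, then to the one containing
    the canonically smallest vertex.  Vertices with zero closeness to every
    component are grouped by their connectivity among themselves in the
    original graph, so the result always covers every vertex.
    """
    isolated = sorted(set(isolated))
    communities: list[set[str]] = [set(c) for c in nontrivial]
    leftovers: list[str] = []
    for v in isolated:
        best: tuple | None = None
        best_idx = -1
        for idx, comp in enumerate(nontrivial):
            shared = sum(1 for u in g_original[v] if u in comp)
            if shared == 0:
                continue
            key = (Fraction(shared, len(comp)), shared, _ReverseStr(min(comp)))
            if best is None or key > best:
                best, best_idx = key, idx
        if best is None:
            leftovers.append(v)
        else:
            communities[best_idx].add(v)
    if leftovers:
        sub = g_original.subgraph(leftovers)
        communities.extend(set(c) for c in nx.connected_components(sub))
    return Partition.from_communities(communities)


class _ReverseStr(str):
    """String whose ordering is reversed, for use inside max-keyed tuples."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def run_each(g: nx.Graph, handle_isolated: bool = True) -> EACHResult:
    """Run the full detector on *g*.

    With ``handle_isolated=True`` (EACH) isolated vertices are re-attached;
    with ``False`` (the EAC variant) they become singleton communities.
    """
    residual, removals = removal_loop(g)
    nontrivial, isolated = component_partition(residual)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot detect communities in an empty graph")
    if handle_isolated and nontrivial:
        partition = attach_isolated(nontrivial, isolated, g)
    else:
        communities: list[set[str]] = [set(c) for c in nontrivial]
        communities.extend({v} for v in isolated)
        partition = Partition.from_communities(communities)
    m = g.number_of_edges()
    rr = Fraction(len(removals), m) if m else Fraction(0)
    comps = tuple(
        sorted(
            (frozenset(c) for c in nx.connected_components(residual)),
            key=min,
        )
    )
    return EACHResult(
        removals=removals,
        residual_components=comps,
        partition=partition,
        rr=rr,
        noc=partition.k,
    )
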