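"""Graph data model, readers/writers, and bundled example networks.

Graphs are plain :class:`networkx.Graph` objects restricted to the simple,
undirected, unweighted case.  Vertex labels are opaque strings; the canonical
total order on labels is plain lexicographic comparison, and an *edge key* is
the lexicographically sorted pair ``(u, v)``.  Every score map in this package
is keyed by canonical edge keys so that scores are unambiguous.

Disconnected graphs are accepted everywhere; operations treat connected
components independently, which leaves results on connected inputs unchanged.
"""

from __future__ import annotations

import io
from importlib import resources
from typing import IO, Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "EdgeKey",
    "EdgeListParseError",
    "GraphValidationError",
    "Partition",
    "canonical_edge",
    "edge_keys",
    "read_edge_list",
    "read_graph",
    "read_labels",
    "write_partition",
    "load_fixture",
    "FIXTURE_NAMES",
    "WORKED_EXAMPLE_EDGE",
]

EdgeKey = tuple[str, str]


class EdgeListParseError(ValueError):
    """A line of an edge-list or label file could not be parsed."""


class GraphValidationError(ValueError):
    """Input violates the simple-undirected-graph (or partition) contract."""


def canonical_edge(u: str, v: str) -> EdgeKey:
    """Return the canonical (lexicographically sorted) key for edge ``{u, v}``."""
    u, v = str(u), str(v)
    return (u, v) if u <= v else (v, u)


def edge_keys(g: nx.Graph) -> Iterator[EdgeKey]:
    """Iterate over the canonical keys of every edge of *g* (arbitrary order)."""
    for u, v in g.edges():
        yield canonical_edge(u, v)


def validate_graph(g: nx.Graph) -> None:
    """Raise :class:`GraphValidationError` if *g* is not simple and undirected."""
    if g.is_directed() or g.is_multigraph():
        raise GraphValidationError("graph must be simple and undirected")
    loops = [v for v, u in nx.selfloop_edges(g)]
    if loops:
        raise GraphValidationError(f"self-loops are not allowed: {loops[:5]}")


class Partition:
    """An assignment of every vertex to exactly one community.

    Community identifiers are normalized to the contiguous range ``1..K``,
    numbering communities by their lexicographically smallest member, so two
    partitions that group vertices identically compare equal regardless of the
    raw labels they were built from.
    """

    __slots__ = ("_assign", "_communities")

    def __init__(self, mapping: Mapping[str, object]):
        if not mapping:
            raise GraphValidationError("partition must cover at least one vertex")
        groups: dict[object, set[str]] = {}
        for v, c in mapping.items():
            groups.setdefault(c, set()).add(str(v))
        ordered = sorted(groups.values(), key=lambda s: min(s))
        self._communities: tuple[frozenset[str], ...] = tuple(
            frozenset(s) for s in ordered
        )
        self._assign: dict[str, int] = {}
        for cid, members in enumerate(self._communities, start=1):
            for v in members:
                self._assign[v] = cid

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable[str]]) -> "Partition":
        mapping: dict[str, int] = {}
        for cid, members in enumerate(communities, start=1):
            for v in members:
                v = str(v)
                if v in mapping:
                    raise GraphValidationError(f"vertex {v!r} appears in two communities")
            for v in members:
                mapping[str(v)] = cid
        return cls(mapping)

    @property
    def k(self) -> int:
        """Number of communities K."""
        return len(self._communities)

    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(self._assign)

    def communities(self) -> tuple[frozenset[str], ...]:
        """Communities ordered by their normalized id 1..K."""
        return self._communities

    def __getitem__(self, vertex: str) -> int:
        return self._assign[str(vertex)]

    def as_dict(self) -> dict[str, int]:
        return dict(self._assign)

    def __len__(self) -> int:
        return len(self._assign)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return frozenset(self._communities) == frozenset(other._communities)

    def __hash__(self) -> int:
        return hash(frozenset(self._communities))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Partition(K={self.k}, N={len(self)})"


def _as_lines(stream: IO[str] | str) -> Iterator[tuple[int, str]]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for lineno, raw in enumerate(stream, start=1):
        yield lineno, raw


def read_edge_list(stream: IO[str] | str, comment_prefix: str = "#") -> nx.Graph:
    """Read a whitespace-delimited edge list into a simple undirected graph.

    Each non-blank, non-comment line must hold exactly two vertex labels.
    Duplicate lines and reversed duplicates collapse to a single edge;
    self-loop lines are rejected.
    """
    g = nx.Graph()
    for lineno, raw in _as_lines(stream):
        line = raw.strip()
        if not line or line.startswith(comment_prefix):
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise EdgeListParseError(
                f"line {lineno}: expected 2 vertex labels, got {len(tokens)}: {line!r}"
            )
        u, v = tokens
        if u == v:
            raise GraphValidationError(f"line {lineno}: self-loop {u!r}-{v!r} rejected")
        g.add_edge(u, v)
    return g


def read_graph(path: str, fmt: str | None = None) -> nx.Graph:
    """Read a graph from *path*: ``edgelist`` (default) or ``gml``."""
    if fmt is None:
        fmt = "gml" if str(path).lower().endswith(".gml") else "edgelist"
    if fmt == "gml":
        g = nx.read_gml(str(path), label="label")
        g = nx.relabel_nodes(nx.Graph(g), {v: str(v) for v in g})
        validate_graph(g)
        return g
    if fmt == "edgelist":
        with open(path, "r", encoding="utf-8") as fh:
            return read_edge_list(fh)
    raise ValueError(f"unknown graph format {fmt!r}")


def read_labels(stream: IO[str] | str) -> Partition:
    """Read a two-column (vertex, community-id) table into a :class:`Partition`."""
    raw_assign: dict[str, str] = {}
    for lineno, line in _as_lines(stream):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise EdgeListParseError(
                f"line {lineno}: expected 'vertex community', got {line!r}"
            )
        v, c = tokens
        if v in raw_assign and raw_assign[v] != c:
            raise GraphValidationError(
                f"line {lineno}: vertex {v!r} labelled {c!r} but already {raw_assign[v]!r}"
            )
        raw_assign[v] = c
    if not raw_assign:
        raise GraphValidationError("label table is empty")
    return Partition(raw_assign)


def write_partition(p: Partition, stream: IO[str]) -> None:
    """Write *p* as tab-separated ``vertex<TAB>community`` lines, vertex-sorted."""
    for v in sorted(p.vertices):
        stream.write(f"{v}\t{p[v]}\n")


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("karate", "worked_example", "two_triangle_bridge", "path4")

#: Canonical key of the scored edge of the ``worked_example`` fixture: the
#: inter-community edge for which the antitriangle counts are 24 potential
#: and 10 induced four-vertex paths, hence a centrality score of 2/5.
WORKED_EXAMPLE_EDGE: EdgeKey = ("i", "j")


def _data_text(name: str) -> str:
    return resources.files(__package__).joinpath("data", name).read_text("utf-8")


def load_fixture(name: str) -> tuple[nx.Graph, Partition | None]:
    """Load a bundled example graph (and its reference partition, if any).

    ``karate``
        Zachary's 34-member karate club (78 edges) with its two observed
        factions as ground truth.
    ``worked_example``
        A small two-community graph whose marked inter-community edge
        (:data:`WORKED_EXAMPLE_EDGE`) has 24 potential and 10 induced
        four-vertex paths, the illustrative numbers for the antitriangle
        centrality.  No reference partition.
    ``two_triangle_bridge``
        Two triangles {1,2,3} and {4,5,6} joined by the bridge 3-4, with the
        planted two-community partition.
    ``path4``
        The path a-b-c-d; no reference partition.
    """
    if name == "karate":
        g = read_edge_list(_data_text("karate.edges"))
        p = read_labels(_data_text("karate_factions.tsv"))
        return g, p
    if name == "worked_example":
        return read_edge_list(_data_text("worked_example_synthetic.edges")), None
    if name == "two_triangle_bridge":
        g = read_edge_list("1 2\n1 3\n2 3\n4 5\n4 6\n5 6\n3 4\n")
        p = Partition({"1": 1, "2": 1, "3": 1, "4": 2, "5": 2, "6": 2})
        return g, p
    if name == "path4":
        return read_edge_list("a b\nb c\nc d\n"), None
    raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
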