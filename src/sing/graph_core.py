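"""Graph data model and gSpan transaction-format I/O.

The unit of data everywhere in this package is an undirected graph whose
vertices carry opaque string labels (atomic symbols, expression-level bins,
protein-cluster ids -- anything).  Databases, queries and generated fixtures
are all exchanged in the gSpan transaction text format::

    t # <graph id>
    v <index> <label>
    e <u> <v>

Vertex indices within a graph are 0-based and must appear in order 0..n-1;
all ``v`` lines of a graph precede its ``e`` lines.  Lines starting with
``#`` (other than the ``#`` inside ``t # id``) are comments.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

__all__ = [
    "LabeledGraph",
    "GraphDB",
    "GspanParseError",
    "GraphValidationError",
    "parse_gspan",
    "write_gspan",
]


class GspanParseError(ValueError):
    """A line of gSpan input could not be parsed; carries the line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


class GraphValidationError(ValueError):
    """Structural violation: self-loop, duplicate edge, or bad vertex index."""


class LabeledGraph:
    """An undirected vertex-labeled graph g = (V, E, Sigma, l).

    Edges are stored once as unordered pairs (u, v) with u < v; adjacency
    queries answer identically for both orientations.  Self-loops and
    duplicate edges are rejected at construction.
    """

    __slots__ = ("graph_id", "_labels", "_edges", "_adj")

    def __init__(
        self,
        graph_id: str,
        labels: Sequence[str],
        edges: Iterable[tuple[int, int]] = (),
    ):
        self.graph_id = str(graph_id)
        self._labels: tuple[str, ...] = tuple(str(x) for x in labels)
        n = len(self._labels)
        seen: set[tuple[int, int]] = set()
        adj: list[list[int]] = [[] for _ in range(n)]
        for u, v in edges:
            if not (0 <= u < n and 0 <= v < n):
                raise GraphValidationError(
                    f"graph {graph_id!r}: edge ({u},{v}) references an "
                    f"undeclared vertex (n={n})"
                )
            if u == v:
                raise GraphValidationError(
                    f"graph {graph_id!r}: self-loop at vertex {u}"
                )
            key = (u, v) if u < v else (v, u)
            if key in seen:
                raise GraphValidationError(
                    f"graph {graph_id!r}: duplicate edge {key}"
                )
            seen.add(key)
            adj[u].append(v)
            adj[v].append(u)
        self._edges = frozenset(seen)
        self._adj: tuple[tuple[int, ...], ...] = tuple(
            tuple(sorted(a)) for a in adj
        )

    # -- basic accessors -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self._labels)

    @property
    def n_edges(self) -> int:
        """size(g) = |E|."""
        return len(self._edges)

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    @property
    def edges(self) -> frozenset[tuple[int, int]]:
        """Edges as (u, v) pairs with u < v."""
        return self._edges

    def label(self, v: int) -> str:
        return self._labels[v]

    def neighbors(self, v: int) -> tuple[int, ...]:
        """Neighbors of v in ascending index order."""
        return self._adj[v]

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def has_edge(self, u: int, v: int) -> bool:
        return ((u, v) if u < v else (v, u)) in self._edges

    def label_set(self) -> frozenset[str]:
        return frozenset(self._labels)

    def is_connected(self) -> bool:
        """True for the empty and single-vertex graph; BFS otherwise."""
        n = self.n_vertices
        if n <= 1:
            return True
        seen = bytearray(n)
        seen[0] = 1
        stack = [0]
        count = 1
        while stack:
            u = stack.pop()
            for w in self._adj[u]:
                if not seen[w]:
                    seen[w] = 1
                    count += 1
                    stack.append(w)
        return count == n

    # -- equality / repr -------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledGraph):
            return NotImplemented
        return (
            self.graph_id == other.graph_id
            and self._labels == other._labels
            and self._edges == other._edges
        )

    def __hash__(self) -> int:
        return hash((self.graph_id, self._labels, self._edges))

    def __repr__(self) -> str:
        return (
            f"LabeledGraph(id={self.graph_id!r}, n={self.n_vertices}, "
            f"m={self.n_edges})"
        )


class GraphDB:
    """An ordered database of :class:`LabeledGraph` with unique graph ids."""

    __slots__ = ("_graphs", "_by_id")

    def __init__(self, graphs: Iterable[LabeledGraph] = ()):
        self._graphs: list[LabeledGraph] = list(graphs)
        self._by_id: dict[str, LabeledGraph] = {}
        for g in self._graphs:
            if g.graph_id in self._by_id:
                raise GraphValidationError(
                    f"duplicate graph id {g.graph_id!r} in database"
                )
            self._by_id[g.graph_id] = g

    @property
    def graphs(self) -> list[LabeledGraph]:
        return list(self._graphs)

    @property
    def graph_ids(self) -> list[str]:
        return [g.graph_id for g in self._graphs]

    @property
    def alphabet(self) -> frozenset[str]:
        """The observed label alphabet: the union of member label sets."""
        out: set[str] = set()
        for g in self._graphs:
            out |= g.label_set()
        return frozenset(out)

    def __len__(self) -> int:
        return len(self._graphs)

    def __iter__(self) -> Iterator[LabeledGraph]:
        return iter(self._graphs)

    def __getitem__(self, graph_id: str) -> LabeledGraph:
        return self._by_id[graph_id]

    def __contains__(self, graph_id: str) -> bool:
        return graph_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GraphDB):
            return NotImplemented
        return self._graphs == other._graphs

    def __repr__(self) -> str:
        return f"GraphDB(n_graphs={len(self._graphs)})"


def parse_gspan(text: str | Iterable[str]) -> GraphDB:
    """Parse gSpan transaction text into a :class:`GraphDB`.

    ``text`` may be a string or an iterable of lines.  Graphs are returned
    in file order; labels are kept verbatim as strings.  Raises
    :class:`GspanParseError` on malformed lines and
    :class:`GraphValidationError` on structural violations.
    """
    if isinstance(text, str):
        lines: Iterable[str] = text.splitlines()
    else:
        lines = (ln.rstrip("\n") for ln in text)

    graphs: list[LabeledGraph] = []
    cur_id: str | None = None
    cur_labels: list[str] = []
    cur_edges: list[tuple[int, int]] = []
    edges_started = False

    def flush() -> None:
        nonlocal cur_id, cur_labels, cur_edges, edges_started
        if cur_id is not None:
            graphs.append(LabeledGraph(cur_id, cur_labels, cur_edges))
        cur_id, cur_labels, cur_edges = None, [], []
        edges_started = False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "t":
            if len(parts) < 3 or parts[1] != "#":
                raise GspanParseError(lineno, f"malformed t line: {line!r}")
            flush()
            cur_id = " ".join(parts[2:])
        elif line.startswith("#"):
            continue  # comment
        elif parts[0] == "v":
            if cur_id is None:
                raise GspanParseError(lineno, "v line before any t line")
            if edges_started:
                raise GspanParseError(lineno, "v line after e lines")
            if len(parts) < 3:
                raise GspanParseError(lineno, f"malformed v line: {line!r}")
            try:
                idx = int(parts[1])
            except ValueError:
                raise GspanParseError(
                    lineno, f"non-integer vertex index: {parts[1]!r}"
                ) from None
            if idx != len(cur_labels):
                raise GspanParseError(
                    lineno,
                    f"vertex index {idx} out of order "
                    f"(expected {len(cur_labels)})",
                )
            cur_labels.append(" ".join(parts[2:]))
        elif parts[0] == "e":
            if cur_id is None:
                raise GspanParseError(lineno, "e line before any t line")
            if len(parts) != 3:
                raise GspanParseError(lineno, f"malformed e line: {line!r}")
            try:
                u, v = int(parts[1]), int(parts[2])
            except ValueError:
                raise GspanParseError(
                    lineno, f"non-integer edge endpoint in: {line!r}"
                ) from None
            edges_started = True
            cur_edges.append((u, v))
        else:
            raise GspanParseError(lineno, f"unrecognized line: {line!r}")
    flush()
    return GraphDB(graphs)


def write_gspan(db: GraphDB | LabeledGraph) -> str:
    """Serialize a database (or single graph) to canonical gSpan text.

    Per graph: the ``t`` line, ``v`` lines in ascending index, then ``e``
    lines with u < v sorted lexicographically.  Output is byte-stable:
    ``write(parse(x))`` is identical for any two structurally equal inputs.
    """
    if isinstance(db, LabeledGraph):
        db = GraphDB([db])
    out: list[str] = []
    for g in db:
        out.append(f"t # {g.graph_id}")
        for i, lab in enumerate(g.labels):
            out.append(f"v {i} {lab}")
        for u, v in sorted(g.edges):
            out.append(f"e {u} {v}")
    return "\n".join(out) + ("\n" if out else "")
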