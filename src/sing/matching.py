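"""Verification: VF2-style backtracking constrained by the compatibility map.

The matcher enumerates subgraph isomorphisms under monomorphism semantics:
an injective map phi from query vertices to target vertices that preserves
labels and carries every query edge to a target edge (query non-edges
impose no constraint).  Where classic VF2 tests per-pair semantic
compatibility by label comparison, here a candidate pair (v, u) is
admissible only if u is in M[v] — the locality filter's per-vertex set of
target vertices from which every feature starting at v also starts.  Any
true isomorphism maps v inside M[v], so shrinking the candidate sets never
loses a match; it only narrows the search tree.

Query vertices are matched in a static connectivity-respecting order chosen
once from the popcounts of the supplied candidate sets (rarest first, ties
by lowest index; each subsequent vertex must be adjacent to an earlier
one).  Keeping the order a pure function of the supplied map — and allowing
an explicit override — makes search-tree sizes directly comparable across
different candidate maps under one ordering.  Explored-state counts (one
state per partial-match extension) are exposed via :class:`MatchStats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .graph_core import GraphDB, LabeledGraph
from .index import SingIndex
from .filtering import first_step_filter, second_step_filter
from .path_features import query_features

__all__ = [
    "Match",
    "MatchStats",
    "QueryResult",
    "UnsupportedQueryError",
    "label_compatibility_map",
    "match_order",
    "locality_vf2",
    "run_query",
]

# phi as a tuple: query vertex i -> target vertex Match[i].
Match = tuple[int, ...]


class UnsupportedQueryError(ValueError):
    """Raised for disconnected queries (out of scope for the matcher)."""


@dataclass
class MatchStats:
    """Instrumentation: number of search states (partial-match extensions)."""

    states: int = 0


@dataclass
class QueryResult:
    """Outcome of a database query plus filtering/matching counters."""

    mode: str
    matches: dict[str, list[Match]]  # graph_id -> matches (1 in first mode)
    fq_size: int = 0
    c1: list[str] = field(default_factory=list)
    c2: list[str] = field(default_factory=list)
    m_popcounts: dict[str, list[int]] = field(default_factory=dict)
    states: int = 0

    @property
    def matched_ids(self) -> list[str]:
        return list(self.matches)


def label_compatibility_map(q: LabeledGraph, g: LabeledGraph) -> list[int]:
    """Plain-VF2 semantic compatibility: m[v] = {u : l_g(u) = l_q(v)}.

    The baseline the locality map is measured against; also usable to run
    the matcher without an index.
    """
    by_label: dict[str, int] = {}
    for u in range(g.n_vertices):
        by_label[g.label(u)] = by_label.get(g.label(u), 0) | (1 << u)
    return [by_label.get(q.label(v), 0) for v in range(q.n_vertices)]


def match_order(q: LabeledGraph, m: Sequence[int]) -> list[int]:
    """Static query-vertex ordering: rarest candidate set first, then
    greedily among vertices adjacent to those already ordered (ties by
    lowest index).  Requires a connected query."""
    n = q.n_vertices
    if n == 0:
        return []
    if not q.is_connected():
        raise UnsupportedQueryError(
            "disconnected query graphs are not supported"
        )
    pop = [m[v].bit_count() for v in range(n)]
    first = min(range(n), key=lambda v: (pop[v], v))
    order = [first]
    chosen = {first}
    frontier = set(q.neighbors(first))
    while len(order) < n:
        v = min(frontier - chosen, key=lambda v: (pop[v], v))
        order.append(v)
        chosen.add(v)
        frontier |= set(q.neighbors(v))
    return order


def locality_vf2(
    q: LabeledGraph,
    g: LabeledGraph,
    m: Sequence[int],
    mode: str = "all",
    order: Sequence[int] | None = None,
    stats: MatchStats | None = None,
) -> Iterator[Match]:
    """Lazily enumerate subgraph isomorphisms of q into g restricted by m.

    ``m[v]`` is an integer bitset of admissible target vertices for query
    vertex v.  In ``all`` mode every distinct mapping is produced (automorphic
    images count separately); in ``first`` mode enumeration stops after one.
    Enumeration order is deterministic: target candidates ascend, query
    vertices follow ``order`` (default: :func:`match_order` on ``m``).
    """
    if mode not in ("first", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    nq = q.n_vertices
    if order is None:
        order = match_order(q, m)
    else:
        order = list(order)
        if sorted(order) != list(range(nq)):
            raise ValueError("order must be a permutation of query vertices")
        if nq and not q.is_connected():
            raise UnsupportedQueryError(
                "disconnected query graphs are not supported"
            )
    if stats is None:
        stats = MatchStats()

    if nq == 0:
        yield ()
        return

    # Target adjacency as bitsets for O(1) edge-consistency via AND.
    g_adj = [0] * g.n_vertices
    for u, w in g.edges:
        g_adj[u] |= 1 << w
        g_adj[w] |= 1 << u

    # For the vertex at position i, its query neighbors at earlier positions.
    pos_of = {v: i for i, v in enumerate(order)}
    earlier: list[list[int]] = []
    for i, v in enumerate(order):
        earlier.append([w for w in q.neighbors(v) if pos_of[w] < i])

    assignment = [-1] * nq
    used = 0

    def extend(i: int) -> Iterator[Match]:
        nonlocal used
        v = order[i]
        cand = m[v] & ~used
        for w in earlier[i]:
            cand &= g_adj[assignment[w]]
            if not cand:
                return
        while cand:
            low = cand & -cand
            cand ^= low
            u = low.bit_length() - 1
            stats.states += 1
            assignment[v] = u
            used |= low
            if i + 1 == nq:
                yield tuple(assignment)
            else:
                yield from extend(i + 1)
            used ^= low
            assignment[v] = -1

    for phi in extend(0):
        yield phi
        if mode == "first":
            return


def run_query(
    index: SingIndex,
    db: GraphDB,
    q: LabeledGraph,
    mode: str = "all",
    max_matches: int | None = None,
) -> QueryResult:
    """Full pipeline: query features -> C1 -> C2 + M -> constrained VF2.

    ``max_matches`` caps the number of matches reported per graph in
    ``all`` mode.  An empty query matches every graph with the empty
    mapping.  Raises ValueError when the index does not describe ``db``.
    """
    if index.graph_order != db.graph_ids or any(
        index.n_vertices[g.graph_id] != g.n_vertices for g in db
    ):
        raise ValueError("index does not match the supplied database")
    qf = query_features(q, index.params.lp)
    c1 = first_step_filter(index, qf.fq)
    c2, m = second_step_filter(index, qf.fvq, c1)
    stats = MatchStats()
    matches: dict[str, list[Match]] = {}
    for gid in c2:
        g = db[gid]
        found: list[Match] = []
        for phi in locality_vf2(q, g, m[gid], mode=mode, stats=stats):
            found.append(phi)
            if mode == "first":
                break
            if max_matches is not None and len(found) >= max_matches:
                break
        if found:
            matches[gid] = found
    return QueryResult(
        mode=mode,
        matches=matches,
        fq_size=len(qf.fq),
        c1=c1,
        c2=c2,
        m_popcounts={
            gid: [bits.bit_count() for bits in entry]
            for gid, entry in m.items()
        },
        states=stats.states,
    )
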