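"""Bounded-length simple-path label features.

A *path feature* is the ordered sequence of labels spelled by a simple path
(all vertices distinct).  An *occurrence* of a feature is a distinct directed
vertex sequence spelling it, so an undirected path is counted once per
orientation; the occurrence's *start* is its first vertex.  Path length is
counted in vertices: a k-length path has k vertices and k-1 edges, and the
enumeration bound ``lp`` caps the number of vertices (default 4).

Two summaries are computed per database graph:

* occurrence counts  — how many occurrences each feature has (the global
  index stores these, enabling count-based pruning: if the query has n
  occurrences of f and g has fewer, g cannot contain the query);
* start bitsets      — ``start(f, g)``, the set of vertices from which an
  occurrence of f begins, packed as an integer bitset (the local index).

Queries are summarized differently: only *maximal* enumerated occurrences
(those that cannot be extended — depth ``lp`` reached or dead end) are
recorded, which keeps the query feature set small while remaining a valid
lower bound on true occurrence counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .graph_core import LabeledGraph

__all__ = [
    "PathFeature",
    "QueryFeatures",
    "enumerate_start_paths",
    "occurrence_counts",
    "start_bitsets",
    "graph_features",
    "query_features",
]

# A path feature is just a tuple of labels; tuples are hashable and order
# lexicographically, which the index serialization relies on.
PathFeature = tuple[str, ...]

DEFAULT_LP = 4  # max path length in vertices


def _for_each_occurrence(
    g: LabeledGraph,
    v: int,
    lp: int,
    emit: Callable[[PathFeature, bool], None],
) -> None:
    """Depth-first enumeration of simple paths with <= lp vertices from v.

    Calls ``emit(labels, terminal)`` exactly once per directed simple vertex
    sequence; ``terminal`` is True when the sequence cannot be extended
    (depth lp reached, or every neighbor of the tip is already on the path).
    Neighbors are explored in ascending index order; this affects only
    emission order, never the set of occurrences.
    """
    labels = g.labels
    adj = g.neighbors
    on_path = bytearray(g.n_vertices)
    spelled: list[str] = [labels[v]]
    on_path[v] = 1

    def rec(u: int, depth: int) -> None:
        extended = False
        if depth < lp:
            for w in adj(u):
                if not on_path[w]:
                    extended = True
                    on_path[w] = 1
                    spelled.append(labels[w])
                    rec(w, depth + 1)
                    spelled.pop()
                    on_path[w] = 0
        emit(tuple(spelled), not extended)

    rec(v, 1)


def enumerate_start_paths(
    g: LabeledGraph, v: int, lp: int
) -> list[tuple[PathFeature, bool]]:
    """All (label sequence, terminal flag) pairs for simple paths from v.

    One entry per directed simple vertex sequence starting at v with at
    most ``lp`` vertices, so the same label sequence may appear repeatedly
    (once per occurrence).
    """
    if not 0 <= v < g.n_vertices:
        raise IndexError(f"vertex {v} out of range for n={g.n_vertices}")
    if lp < 1:
        raise ValueError("lp must be >= 1")
    out: list[tuple[PathFeature, bool]] = []
    _for_each_occurrence(g, v, lp, lambda f, t: out.append((f, t)))
    return out


def occurrence_counts(g: LabeledGraph, lp: int) -> dict[PathFeature, int]:
    """Number of occurrences of every feature of length <= lp contained in g.

    Features not contained in g are absent; all stored counts are >= 1.
    """
    counts, _ = graph_features(g, lp)
    return counts


def start_bitsets(g: LabeledGraph, lp: int) -> dict[PathFeature, int]:
    """start(f, g) for every contained feature, as integer bitsets.

    Bit v is set iff some occurrence of f starts at vertex v.  Start sets
    are prefix-closed: if f is a prefix of f', start(f', g) ⊆ start(f, g).
    """
    _, starts = graph_features(g, lp)
    return starts


def graph_features(
    g: LabeledGraph, lp: int
) -> tuple[dict[PathFeature, int], dict[PathFeature, int]]:
    """Occurrence counts and start bitsets in one enumeration pass."""
    if lp < 1:
        raise ValueError("lp must be >= 1")
    counts: dict[PathFeature, int] = {}
    starts: dict[PathFeature, int] = {}
    for v in range(g.n_vertices):
        bit = 1 << v

        def emit(f: PathFeature, _terminal: bool, bit: int = bit) -> None:
            counts[f] = counts.get(f, 0) + 1
            starts[f] = starts.get(f, 0) | bit

        _for_each_occurrence(g, v, lp, emit)
    return counts, starts


@dataclass(frozen=True)
class QueryFeatures:
    """Feature summary of a query graph.

    ``fq`` maps each feature with at least one maximal occurrence to the
    number of its maximal occurrences — a lower bound on the feature's true
    occurrence count in the query, which is what count-based pruning needs.
    ``fvq[v]`` is the set of features having a maximal occurrence starting
    at vertex v; it is nonempty for every vertex (an isolated vertex
    contributes its single-label path).
    """

    fq: dict[PathFeature, int]
    fvq: tuple[frozenset[PathFeature], ...]


def query_features(q: LabeledGraph, lp: int) -> QueryFeatures:
    """Extract FQ (maximal-occurrence counts) and FVQ (per-vertex features).

    Only maximal enumerated occurrences are recorded: occurrences that are
    proper prefixes of a longer occurrence on the same branch are dropped.
    A feature may still appear both on its own and as a prefix of another
    recorded feature via different branches; that is harmless because the
    recorded counts are lower bounds.
    """
    if lp < 1:
        raise ValueError("lp must be >= 1")
    fq: dict[PathFeature, int] = {}
    fvq: list[set[PathFeature]] = [set() for _ in range(q.n_vertices)]
    for v in range(q.n_vertices):

        def emit(f: PathFeature, terminal: bool, v: int = v) -> None:
            if terminal:
                fq[f] = fq.get(f, 0) + 1
                fvq[v].add(f)

        _for_each_occurrence(q, v, lp, emit)
    return QueryFeatures(fq=fq, fvq=tuple(frozenset(s) for s in fvq))
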