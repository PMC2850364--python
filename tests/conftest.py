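"""Shared fixtures, hypothesis strategies, and independent test oracles.

The path-feature oracle here enumerates simple vertex sequences by brute
force over ``itertools.permutations`` — deliberately nothing like the
package's depth-first enumeration — so feature counts and start sets are
checked against an independent computation.
"""

from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import strategies as st

from sing import GraphDB, LabeledGraph

LABELS = ["A", "B", "C"]


# -- independent path-feature oracle -------------------------------------


def oracle_path_counts(g: LabeledGraph, lp: int) -> dict[tuple[str, ...], int]:
    """Occurrence counts via permutation enumeration (independent oracle)."""
    counts: dict[tuple[str, ...], int] = {}
    n = g.n_vertices
    for k in range(1, lp + 1):
        for seq in itertools.permutations(range(n), k):
            if all(g.has_edge(seq[i], seq[i + 1]) for i in range(k - 1)):
                f = tuple(g.label(v) for v in seq)
                counts[f] = counts.get(f, 0) + 1
    return counts


def oracle_start_sets(g: LabeledGraph, lp: int) -> dict[tuple[str, ...], int]:
    """Start bitsets via permutation enumeration (independent oracle)."""
    starts: dict[tuple[str, ...], int] = {}
    n = g.n_vertices
    for k in range(1, lp + 1):
        for seq in itertools.permutations(range(n), k):
            if all(g.has_edge(seq[i], seq[i + 1]) for i in range(k - 1)):
                f = tuple(g.label(v) for v in seq)
                starts[f] = starts.get(f, 0) | (1 << seq[0])
    return starts


# -- random graph construction -------------------------------------------


def random_graph(
    rng: random.Random,
    n_min: int = 1,
    n_max: int = 10,
    labels: list[str] = LABELS,
    edge_p: float = 0.3,
    gid: str = "g",
    connected: bool = False,
) -> LabeledGraph:
    n = rng.randint(n_min, n_max)
    labs = [rng.choice(labels) for _ in range(n)]
    edges: set[tuple[int, int]] = set()
    if connected:
        for i in range(1, n):
            j = rng.randrange(i)
            edges.add((j, i))
    for u in range(n):
        for v in range(u + 1, n):
            if rng.random() < edge_p:
                edges.add((u, v))
    return LabeledGraph(gid, labs, edges)


# -- hypothesis strategies ------------------------------------------------


@st.composite
def labeled_graphs(draw, max_n: int = 8, labels: tuple[str, ...] = ("A", "B", "C")):
    n = draw(st.integers(min_value=1, max_value=max_n))
    labs = draw(st.lists(st.sampled_from(labels), min_size=n, max_size=n))
    possible = [(u, v) for u in range(n) for v in range(u + 1, n)]
    edges = draw(st.lists(st.sampled_from(possible), unique=True, max_size=len(possible))) if possible else []
    return LabeledGraph("h", labs, edges)


# -- canned fixtures -------------------------------------------------------


@pytest.fixture
def star_graph() -> LabeledGraph:
    """a(A)-b(B), b-c1(C), b-c2(C): the (ABC,2)-but-not-(AB,2) instance."""
    return LabeledGraph("star", ["A", "B", "C", "C"], [(0, 1), (1, 2), (1, 3)])


@pytest.fixture
def triangle() -> LabeledGraph:
    return LabeledGraph("tri", ["A", "B", "C"], [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def locality_scenario() -> tuple[GraphDB, LabeledGraph]:
    """db = {g1: path B-A-C, g2: chain B-A-A-C} with query B-A-C.

    Both graphs contain features (A,B) and (A,C), but only in g1 do the
    occurrences start from the same vertex; q embeds in g1 only.
    """
    g1 = LabeledGraph("g1", ["B", "A", "C"], [(0, 1), (1, 2)])
    g2 = LabeledGraph("g2", ["B", "A", "A", "C"], [(0, 1), (1, 2), (2, 3)])
    q = LabeledGraph("q", ["B", "A", "C"], [(0, 1), (1, 2)])
    return GraphDB([g1, g2]), q
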