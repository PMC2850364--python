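"""Synthetic workloads and the brute-force correctness oracle.

Generators emulate the experimental settings the index is meant for:

* :func:`gen_scale_free` — a preferential-attachment network (heavy-tailed
  degrees, a single connected component) with labels drawn uniformly or
  from a frequency vector; the standard single-large-graph workload is
  2000 nodes / ~4000 edges / 8 uniform labels.
* :func:`sample_query_bfs` — queries sampled from a target graph by random
  breadth-first expansion to a fixed edge count, so each query is contained
  in its source graph by construction (workload sizes 4/8/16 edges).
* :func:`gen_molecule_like_db` — databases of many small sparse connected
  graphs with skewed label frequencies, shaped like chemical-compound
  collections.
* :func:`hub_query_fixture` — a pathological pair: a query with a degree-12
  hub and a target whose similar hub neighborhood admits no match, the case
  where locality pruning pays off most.

:func:`brute_force_matches` is the independent oracle: plain exhaustive
enumeration over injective label-preserving assignments, sharing no code
with the feature, filter, or matcher modules.  All generators are pure
functions of their parameters and seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .graph_core import GraphDB, LabeledGraph

__all__ = [
    "GenSpec",
    "brute_force_matches",
    "gen_scale_free",
    "sample_query_bfs",
    "gen_molecule_like_db",
    "hub_query_fixture",
]


def brute_force_matches(
    q: LabeledGraph, g: LabeledGraph, limit: int | None = None
) -> set[tuple[int, ...]]:
    """All subgraph isomorphisms of q into g by exhaustive enumeration.

    Query vertices are assigned in breadth-first order (so each candidate
    is checked against the query edges to already-assigned vertices as soon
    as possible); every injective label-preserving assignment that carries
    all query edges is collected.  ``limit`` stops enumeration early once
    that many matches are found (containment checks use ``limit=1``).
    Intended for small targets; shares no code with the feature, filter or
    matcher modules.
    """
    nq, ng = q.n_vertices, g.n_vertices
    if nq == 0:
        return {()}
    candidates = [
        [u for u in range(ng) if g.label(u) == q.label(v)] for v in range(nq)
    ]
    # BFS order across components keeps partial assignments edge-connected.
    order: list[int] = []
    seen = [False] * nq
    for root in range(nq):
        if seen[root]:
            continue
        seen[root] = True
        queue = [root]
        while queue:
            v = queue.pop(0)
            order.append(v)
            for w in q.neighbors(v):
                if not seen[w]:
                    seen[w] = True
                    queue.append(w)
    results: set[tuple[int, ...]] = set()
    assignment = [-1] * nq
    back_edges = [
        [w for w in order[:i] if q.has_edge(v, w)]
        for i, v in enumerate(order)
    ]

    def rec(i: int, used: set[int]) -> bool:
        if i == nq:
            results.add(tuple(assignment))
            return limit is not None and len(results) >= limit
        v = order[i]
        for u in candidates[v]:
            if u in used:
                continue
            if all(g.has_edge(u, assignment[w]) for w in back_edges[i]):
                assignment[v] = u
                used.add(u)
                done = rec(i + 1, used)
                used.remove(u)
                assignment[v] = -1
                if done:
                    return True
        return False

    rec(0, set())
    return results


@dataclass(frozen=True)
class GenSpec:
    """Parameters of the scale-free generator; the seed fully determines
    the output.  ``label_model`` is "uniform" or a frequency vector (one
    relative weight per label)."""

    n_nodes: int
    n_edges: int
    n_labels: int = 8
    label_model: str | tuple[float, ...] = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.n_edges < self.n_nodes - 1:
            raise ValueError(
                "n_edges must be >= n_nodes - 1 for a connected output"
            )
        if self.n_labels < 1:
            raise ValueError("n_labels must be >= 1")


def _draw_labels(
    rng: random.Random, n: int, n_labels: int, model: str | tuple[float, ...]
) -> list[str]:
    names = [f"L{i}" for i in range(n_labels)]
    if model == "uniform":
        return [rng.choice(names) for _ in range(n)]
    weights = list(model)  # type: ignore[arg-type]
    if len(weights) != n_labels:
        raise ValueError("frequency vector length must equal n_labels")
    return rng.choices(names, weights=weights, k=n)


def gen_scale_free(spec: GenSpec) -> LabeledGraph:
    """Preferential-attachment network: connected, heavy-tailed degrees.

    Nodes are added one at a time, each wired to an existing node with
    probability proportional to degree (plus-one smoothing seeds the
    process); remaining edges are then added with both endpoints chosen
    preferentially, rejecting self-loops and duplicates.
    """
    rng = random.Random(spec.seed)
    n = spec.n_nodes
    edges: set[tuple[int, int]] = set()
    # Every edge endpoint appears once in `ends`, so drawing uniformly from
    # the union of {0..limit-1} and `ends` realizes weight degree+1
    # (plus-one smoothing seeds the process when all degrees are zero).
    ends: list[int] = []

    def pick(limit: int, exclude: int = -1) -> int:
        while True:
            r = rng.randrange(limit + len(ends))
            u = r if r < limit else ends[r - limit]
            if u != exclude:
                return u

    def add(u: int, v: int) -> bool:
        key = (u, v) if u < v else (v, u)
        if u == v or key in edges:
            return False
        edges.add(key)
        ends.append(u)
        ends.append(v)
        return True

    for i in range(1, n):
        add(i, pick(i))
    attempts = 0
    max_attempts = 200 * max(spec.n_edges, 1)
    while len(edges) < spec.n_edges:
        u = pick(n)
        v = pick(n, exclude=u)
        if not add(u, v):
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"could not place {spec.n_edges} distinct edges on "
                    f"{n} nodes"
                )
    labels = _draw_labels(rng, n, spec.n_labels, spec.label_model)
    return LabeledGraph(f"sf-{spec.seed}", labels, edges)


def sample_query_bfs(
    g: LabeledGraph,
    t_edges: int,
    seed: int = 0,
    max_retries: int = 50,
    query_id: str | None = None,
) -> LabeledGraph:
    """A connected t-edge query sampled from g by random BFS expansion.

    Starting from a random vertex, repeatedly adds a random frontier edge
    (an unused edge of g touching the sampled vertex set) until ``t_edges``
    are collected, restarting from a fresh vertex on dead ends.  The result
    is a relabeled copy of a subgraph of g, so it is contained in g by
    construction.
    """
    if t_edges < 1:
        raise ValueError("t_edges must be >= 1")
    if g.n_edges < t_edges:
        raise ValueError(f"graph has only {g.n_edges} edges, need {t_edges}")
    rng = random.Random(seed)
    for _attempt in range(max_retries):
        start = rng.randrange(g.n_vertices)
        vertices: list[int] = [start]
        vset = {start}
        chosen: list[tuple[int, int]] = []
        cset: set[tuple[int, int]] = set()
        while len(chosen) < t_edges:
            frontier = sorted(
                (min(v, w), max(v, w))
                for v in vertices
                for w in g.neighbors(v)
                if (min(v, w), max(v, w)) not in cset
            )
            if not frontier:
                break
            e = frontier[rng.randrange(len(frontier))]
            chosen.append(e)
            cset.add(e)
            for end in e:
                if end not in vset:
                    vset.add(end)
                    vertices.append(end)
        if len(chosen) == t_edges:
            remap = {v: i for i, v in enumerate(vertices)}
            qid = query_id or f"q-{g.graph_id}-t{t_edges}-s{seed}"
            return LabeledGraph(
                qid,
                [g.label(v) for v in vertices],
                [(remap[u], remap[v]) for u, v in chosen],
            )
    raise RuntimeError(
        f"failed to sample a {t_edges}-edge query in {max_retries} attempts"
    )


def gen_molecule_like_db(
    n_graphs: int,
    size_range: tuple[int, int] = (10, 40),
    n_labels: int = 8,
    label_skew: float = 2.0,
    seed: int = 0,
) -> GraphDB:
    """Many small sparse connected graphs with skewed label frequencies.

    Each graph is a random spanning tree plus extra random edges, with its
    edge count drawn from ``size_range``.  Label i has relative weight
    ``label_skew ** -i``, so skew 1.0 is uniform and larger values
    concentrate mass on the first label (carbon-like).
    """
    if label_skew <= 0:
        raise ValueError("label_skew must be positive")
    rng = random.Random(seed)
    weights = tuple(label_skew ** -i for i in range(n_labels))
    graphs = []
    for k in range(n_graphs):
        m = rng.randint(*size_range)
        if m == 0:
            n = 1
        else:
            n_min = 2
            while n_min * (n_min - 1) // 2 < m:
                n_min += 1
            n = rng.randint(n_min, m + 1)
        edges: set[tuple[int, int]] = set()
        for i in range(1, n):
            j = rng.randrange(i)
            edges.add((j, i))
        while len(edges) < m:
            u, v = rng.randrange(n), rng.randrange(n)
            if u != v:
                edges.add((min(u, v), max(u, v)))
        labels = _draw_labels(rng, n, n_labels, weights)
        graphs.append(LabeledGraph(f"mol-{k}", labels, edges))
    return GraphDB(graphs)


def hub_query_fixture(seed: int = 0) -> tuple[LabeledGraph, LabeledGraph]:
    """A non-matching hub pair (q, g): the matcher's combinatorial worst case.

    The query has a central hub of degree 12 whose neighbors split into six
    A-leaves and six B-leaves, plus a C pendant hanging off one A-leaf.  The
    target has an identical hub neighborhood but its C pendant hangs off a
    B-leaf, so no embedding exists — yet every label and every short feature
    of the query occurs in the target, forcing a matcher without locality
    information to explore the hub neighborhood combinatorially.  The seed
    shuffles leaf placement only; the oracle finds zero matches for every
    seed.
    """
    rng = random.Random(seed)

    def build(gid: str, pendant_on: str) -> LabeledGraph:
        leaf_labels = ["A"] * 6 + ["B"] * 6
        rng.shuffle(leaf_labels)
        # 0 = hub, 1 = pendant (early index: forces early failure in naive
        # search), 2..13 = leaves.
        labels = ["H", "C"] + leaf_labels
        edges = [(0, i) for i in range(2, 14)]
        host = next(i for i in range(2, 14) if labels[i] == pendant_on)
        edges.append((1, host))
        return LabeledGraph(gid, labels, edges)

    q = build("hub-query", pendant_on="A")
    g = build("hub-target", pendant_on="B")
    return q, g
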