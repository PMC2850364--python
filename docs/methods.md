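# Methods

## Problem and semantics

The package solves two query problems over databases D = {g₁, …, gₙ} of
undirected vertex-labeled graphs: report each g with q ≾ g once with one
embedding (*first* mode), or enumerate every distinct subgraph isomorphism
(*all* mode).  Subgraph semantics are **non-induced** (monomorphism): a
subgraph of g is any (V′ ⊆ V, E′ ⊆ E), so query non-edges impose no
constraint on the target.  Matches are reported as distinct mappings φ;
automorphic images of the same vertex set count separately.  Labels are
opaque strings and the alphabet is simply the observed label set, so
atomic symbols, discretized expression levels and protein-cluster ids all
work unchanged.  Directed and edge-labeled graphs, induced-subgraph
semantics, and approximate matching are out of scope.

## Path features

A path feature is the label sequence spelled by a simple path (all
vertices distinct).  Lengths are counted in **vertices**: a k-length path
has k vertices and k−1 edges, and the enumeration bound `lp` caps the
vertex count, with default `lp = 4` (bounds up to ~10 remain practical;
larger values trade preprocessing time and index size for filtering
power).  Single-vertex paths are included as features — they encode label
counts, and they guarantee that every query vertex has at least one
feature starting at it.

Occurrences are **directed traversals**: an undirected path occurrence is
counted once per orientation.  The convention is applied identically to
database graphs and queries, so the count-pruning inequality
`GI[f][g] ≥ FQ[f]` compares like with like, and occurrence counts are
symmetric under feature reversal (a useful internal consistency check).

Per database graph one depth-first enumeration from each vertex produces
both summaries: occurrence counts (GI) and start bitsets (LI), where
`start(f, g)` is stored as an integer bitset of width |V_g|.  Start sets
are prefix-closed — `start(f′, g) ⊆ start(f, g)` when f is a prefix of f′
— which is what makes indexing only *maximal* query paths lossless for
the locality filter.

Queries record only maximal enumerated occurrences: an occurrence is
maximal when it reaches depth `lp` or a dead end (every neighbor of the
tip already on the path).  Maximality is decided per occurrence, not per
feature, so a feature can appear in FQ and also as a prefix of another FQ
feature via a different branch; since FQ counts are lower bounds on true
occurrence counts, pruning stays sound.  DFS visits neighbors in
ascending vertex index; this affects only enumeration order, never the
counts or sets.

## Filtering

Step 1 intersects GI posting lists, rarest feature first:
`C1 = ⋂_{f∈FQ} {g : GI[f][g] ≥ FQ[f]}`.  An empty FQ (a zero-vertex
query) matches everything by the empty-intersection convention; the
matcher then emits the empty mapping for each graph.  Step 2 computes
`M[g][v] = ⋂_{f∈FVQ[v]} start(f, g)` by bitwise AND over LI rows, only
for C1 survivors; a feature absent from LI[g] short-circuits the
intersection to ∅, and a graph with any empty M[g][v] is discarded.
Because every feature in FVQ[v] begins with the label of v, M[g][v] only
ever contains vertices labeled like v — the classic label-compatibility
test is subsumed.

## Matching

Verification is VF2-style backtracking in which the per-pair semantic
test is membership in M: candidate targets for query vertex v are
`M[g][v]`, minus used vertices, intersected with the adjacency bitsets of
the images of v's already-matched neighbors.  Candidates are tried in
ascending vertex index.

Query vertices are matched in a **static** order fixed before the search:
the vertex with the smallest candidate-set popcount first, then
repeatedly the unordered vertex adjacent to the ordered prefix with the
smallest popcount (ties by lowest index).  A dynamic order (re-ranking by
remaining candidates at every node) can explore slightly fewer states,
but a static order that is a pure function of the supplied candidate map
— plus an explicit `order` override — makes search trees directly
comparable across candidate maps: under one shared order, if
m₁[v] ⊆ m₂[v] for all v, the m₁ search tree is a subtree of the m₂ tree,
so the explored-state count (one state per partial-match extension,
exposed via `MatchStats`) with locality candidates is provably at most
the label-only count.  That nesting property is asserted in the tests and
reported by the acceptance script.

Disconnected queries are rejected explicitly (the connectivity-respecting
order does not extend across components); connected queries cover the
intended workloads.  Enumeration is lazy, deterministic, and stoppable:
*first* mode stops at one match per graph and `--max-matches` caps *all*
mode, which is how very-high-multiplicity queries on large networks are
kept bounded.

## Index serialization

The on-disk index is gzip-compressed JSON with features in lexicographic
label order and graphs in database order, making serialization canonical
and byte-stable (hash-map iteration order never leaks into the file).
Bitsets are packed little-endian (bit v = byte v>>3, bit v&7) and
base64-encoded.  A SHA-256 checksum over the canonical payload detects
corruption and truncation; the format version and the stored `lp` are
validated on load, the latter so that query features are always extracted
at the bound the index was built with.  There are no in-place updates:
the index is rebuilt when the database changes.

## Synthetic workloads

The generators reproduce the settings this kind of index is used in; all
are pure functions of their parameters and seed, emitting byte-identical
output across runs.

* **Scale-free network** (`gen_scale_free`): nodes added one at a time,
  each attached to an existing node with probability proportional to
  degree + 1 (the +1 smoothing seeds the process from degree zero); the
  remaining edges are then added with both endpoints drawn
  preferentially, rejecting self-loops and duplicates.  This guarantees
  connectivity and a heavy-tailed degree distribution (no particular
  power-law exponent is targeted).  The standard single-large-graph
  condition is 2000 nodes, ~4000 edges, 8 labels assigned uniformly at
  random.
* **Query sampling** (`sample_query_bfs`): from a random start vertex,
  repeatedly pick a random unused frontier edge until exactly t edges are
  collected (restarting from a fresh start on dead ends, up to 50 times),
  then relabel to a standalone query.  Sampled queries are contained in
  their source by construction; workload sizes are 4, 8 and 16 edges, 10
  queries per size.
* **Molecule-like database** (`gen_molecule_like_db`): 100 connected
  sparse graphs (random spanning tree plus extra random edges, 10–40
  edges each) with labels drawn from a geometric-weight categorical
  (weight of label i proportional to skew⁻ⁱ, skew 2 by default) —
  emulating collections of small compounds where one label (carbon-like)
  dominates.
* **Hub fixture** (`hub_query_fixture`): a query with a degree-12 hub
  whose neighbors are six A and six B leaves plus a C pendant on an
  A-leaf, and a target identical except the pendant hangs on a B-leaf.
  No embedding exists, every query label and short feature occurs in the
  target, and the hub neighborhood is combinatorially expensive for a
  label-only matcher — the case locality pruning is built for.

What the generators do **not** emulate: real chemical valence rules and
bond multiplicities (multi-edges must be collapsed by whoever produces
the input; the parser rejects them), real degree/label correlations of
curated interaction networks, and label distributions estimated from
data.  Passing tests therefore demonstrate algorithmic correctness and
the expected pruning behavior on structurally similar inputs, not
benchmark performance on any particular public dataset.

## Correctness oracle

`brute_force_matches` enumerates injective label-preserving assignments
in breadth-first query-vertex order with incremental edge checks — no
feature, filter, or compatibility-map code is involved — and anchors
every correctness test: exact match-set equality of the matcher,
zero false negatives of filtering, and Statement-style containment of
every true embedding in M.  It is exponential by design and intended for
small targets (up to ~12 vertices for full enumeration; containment
checks with `limit=1` stay cheap considerably beyond that).

## Numerical and degenerate-input choices

* Bitsets are arbitrary-precision Python integers; popcounts via
  `int.bit_count()`.  No fixed word width.
* Empty database: valid, serializes and round-trips to an index with
  zero features.  Empty query: matches every graph with the empty
  mapping.  Isolated query vertices: carry their single-label feature.
* Ties everywhere break by lowest vertex index, making every pipeline
  stage deterministic for fixed inputs.
* Acceptance-script problem sizes (200 random matcher pairs, a 100-graph
  molecule database with 60 queries, 30 sampled queries on the 2000-node
  network) are the package's chosen verification workloads; they complete
  in seconds while exercising every pipeline stage at the study's stated
  conditions.

## Known limitations

* Path features cannot distinguish some non-isomorphic neighborhoods that
  trees or small graphs would; C2 can contain graphs with no match (the
  matcher settles those).
* The matcher's explored-state guarantee is relative to a shared vertex
  order; a dynamic-order implementation could differ in either direction
  on individual instances.
* Backtracking on pathological label-homogeneous dense graphs is
  exponential in the worst case, as for any exact matcher.
* No incremental index maintenance, secondary-storage paging, or
  frequent-feature mining.
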