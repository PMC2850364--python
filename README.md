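# sing — subgraph search with a path-feature locality index

`sing` answers subgraph-isomorphism queries over databases of vertex-labeled
undirected graphs — chemical compound collections, regulatory and
protein-interaction networks, or any single large labeled graph.  Given a
query graph *q*, it reports the database graphs *g* with *q* ≾ *g* (an
injective, label-preserving map φ: V_q → V_g carrying every query edge to a
target edge), either one embedding per graph (*first* mode) or every
distinct embedding (*all* mode).

Subgraph isomorphism is NP-complete, so the search follows the
filter-and-verify scheme: an offline index prunes graphs that cannot
contain the query, and an exact backtracking matcher verifies the
survivors.  What sets this method apart is **feature locality**: the index
records not only *which* path features each graph contains and how often,
but *where* they start.

## The method

A *path feature* is the label sequence (a₁, …, a_k) spelled by a simple
path; an *occurrence* is a directed vertex sequence spelling it, with start
vertex v₁.  All features up to `lp` vertices (default 4) are enumerated
depth-first per graph, producing two structures:

* **GI** (global index): `GI[f][g]` = number of occurrences of *f* in *g*;
* **LI** (local index): `LI[g][f]` = `start(f, g)` as a bit array over the
  vertices of *g* — bit *v* set iff an occurrence of *f* starts at *v*.

A query is summarized by its *maximal* enumerated path occurrences: `FQ[f]`
counts them per feature (a lower bound on the true occurrence count), and
`FVQ[v]` is the set of features starting at query vertex *v*.  Filtering
then runs in two steps:

1. **Count pruning** — `C1 = ⋂_{f∈FQ} { g ∈ GI[f] : GI[f][g] ≥ FQ[f] }`:
   if the query has more occurrences of some feature than *g*, *g* cannot
   contain it.
2. **Locality pruning** — for each g ∈ C1 and query vertex v,
   `M[g][v] = ⋂_{f∈FVQ[v]} start(f, g)` (a bitwise AND of LI rows).  If
   *q* ≾ *g* via φ, every feature starting at *v* must start at φ(v), so
   `M[g][v] = ∅` for any *v* refutes *g*.

Surviving graphs are verified by a VF2-style backtracking matcher whose
per-vertex semantic test is replaced by membership in `M[g][v]`: φ(v) must
lie in `M[g][v]`, which narrows the search tree without losing any match.
The same machinery handles a database of one large graph, where `M` does
the heavy lifting — e.g. rejecting a high-degree query hub early because
some path starting at the hub starts nowhere in the target's hub
neighborhood.

## Worked example

Index a synthetic 2000-node, ~4000-edge scale-free network with 8 labels,
sample an 8-edge query from it, and search:

```sh
sing generate scale-free --nodes 2000 --edges 4000 --labels 8 --seed 11 --out g.gspan
sing sample-query --graph g.gspan --edges 8 --seed 5 --out q.gspan
sing build --db g.gspan --lp 4 --out g.idx
sing query --index g.idx --db g.gspan --query q.gspan --mode first --explain --out m.tsv
```

The `--explain` line printed to stderr:

```
|FQ|=24 |C1|=1 |C2|=1 matched=1 states=9
M[sf-11] popcounts: [6, 7, 8, 10, 13, 15, 23, 15, 21]
```

The query contributed 24 maximal path features; the single graph passed
both filter steps; the compatibility map left between 6 and 23 admissible
target vertices per query vertex (out of 2000), and the matcher found an
embedding after exploring only 9 search states.  The match line in
`m.tsv` gives φ as `query_vertex->target_vertex` pairs:

```
sf-11	0->84,1->569,2->377,3->546,4->145,5->598,6->37,7->833,8->20
```

Graphs are exchanged in the gSpan transaction format (`t # id`,
`v idx label`, `e u v`; 0-based vertex indices, vertices before edges).

## Index file format

The index is gzip-compressed JSON: an envelope `{"payload": ..., "sha256":
...}` whose payload stores `lp`, the graph ids with vertex counts, the
features in lexicographic order, the GI rows (graph id, count) and the LI
rows as base64 little-endian packed bit arrays (bit *v* = byte `v>>3`, bit
`v&7`).  For a one-graph database `g0` = path A–B–C at `lp=2`:

```json
{"payload": {
   "format": "sing-index", "version": "1", "lp": 2,
   "graphs": [["g0", 3]],
   "features": [["A"], ["A","B"], ["B"], ["B","A"], ["B","C"], ["C"], ["C","B"]],
   "gi": [[["g0",1]], [["g0",1]], [["g0",1]], [["g0",1]], [["g0",1]], [["g0",1]], [["g0",1]]],
   "li": [[[0,"AQ=="], [1,"AQ=="], [2,"Ag=="], [3,"Ag=="], [4,"Ag=="], [5,"BA=="], [6,"BA=="]]]
 },
 "sha256": "..."}
```

`"AQ=="` decodes to byte `0x01` — feature (A) and (A,B) start at vertex 0;
`"Ag=="` is `0x02` (vertex 1), `"BA=="` is `0x04` (vertex 2).  The stored
`lp` is validated whenever the index is loaded, so an index is never
queried at a different path bound than it was built with.

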