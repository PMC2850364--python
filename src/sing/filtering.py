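"""Two-step candidate filtering.

Step 1 (occurrence-count pruning): a database graph survives only if, for
every query feature f, it contains f with at least as many occurrences as
the query —

    C1 = intersection over f in FQ of { g in GI[f] : GI[f][g] >= FQ[f] }.

Step 2 (locality pruning): for each surviving graph g and each query vertex
v, the set of target vertices compatible with v is

    M[g][v] = intersection over f in FVQ[v] of start(f, g),

computed as a bitwise AND of the local-index bit arrays.  If the query is
contained in g, every query vertex must have a compatible target vertex
(every feature starting at v must also start at its image), so a graph with
some M[g][v] empty is discarded.  The surviving M both certifies the filter
decision and later constrains the backtracking matcher.
"""

from __future__ import annotations

from .index import SingIndex
from .path_features import PathFeature

__all__ = ["first_step_filter", "second_step_filter"]

# CompatibilityMap entry for one graph: integer bitset per query vertex.
CompatibilityEntry = list[int]


def first_step_filter(
    index: SingIndex, fq: dict[PathFeature, int]
) -> list[str]:
    """C1: graphs containing every FQ feature with sufficient multiplicity.

    An empty FQ (empty query) matches everything: all graph ids are
    returned, in database order.  A feature absent from GI simply yields an
    empty candidate set.
    """
    if not fq:
        return list(index.graph_order)
    survivors: set[str] | None = None
    # Rarest feature first: smallest GI posting list drives the intersection.
    for f in sorted(fq, key=lambda f: len(index.gi.get(f, {}))):
        need = fq[f]
        having = {g for g, c in index.gi.get(f, {}).items() if c >= need}
        survivors = having if survivors is None else survivors & having
        if not survivors:
            return []
    assert survivors is not None
    return [g for g in index.graph_order if g in survivors]


def second_step_filter(
    index: SingIndex,
    fvq: tuple[frozenset[PathFeature], ...],
    c1: list[str],
) -> tuple[list[str], dict[str, CompatibilityEntry]]:
    """C2 plus the compatibility map M for the survivors.

    Keeps exactly the graphs where M[g][v] is nonempty for every query
    vertex v.  A feature in FVQ[v] missing from LI[g] short-circuits
    M[g][v] to the empty set.
    """
    c2: list[str] = []
    m: dict[str, CompatibilityEntry] = {}
    for gid in c1:
        li_g = index.li[gid]
        full = (1 << index.n_vertices[gid]) - 1
        entry: CompatibilityEntry = []
        alive = True
        for feats in fvq:
            bits = full
            for f in feats:
                got = li_g.get(f)
                if got is None:
                    bits = 0
                    break
                bits &= got
                if not bits:
                    break
            if not bits and feats:
                alive = False
                break
            entry.append(bits)
        if alive:
            c2.append(gid)
            m[gid] = entry
    return c2, m
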