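"""The two-part index: global occurrence counts and local start bitsets.

``GI[f][g]`` is the number of occurrences of path feature f in graph g
(only graphs that contain f appear, so counts are >= 1).  ``LI[g][f]`` is
the start set of f in g as a bit array of length n_vertices(g): bit v is 1
iff an occurrence of f starts at v.  Both structures are produced by one
depth-first enumeration per database graph, bounded at ``lp`` vertices per
path.

On disk the index is a gzip-compressed JSON envelope.  Features are
serialized in lexicographic label order and graphs in database order, so
serialization is canonical; bitsets are packed little-endian (bit v lives
in byte v>>3 at position v&7) and base64-encoded.  A SHA-256 checksum of
the payload guards against truncation/corruption, and the stored ``lp`` is
validated on load so an index is never queried at a different path bound
than it was built with.
"""

from __future__ import annotations

import base64
import gzip
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO

from .graph_core import GraphDB
from .path_features import DEFAULT_LP, PathFeature, graph_features

__all__ = [
    "IndexParams",
    "SingIndex",
    "IndexFormatError",
    "IndexParamsMismatch",
    "build_index",
    "save_index",
    "load_index",
]

FORMAT_VERSION = "1"


class IndexFormatError(ValueError):
    """Corrupt, truncated, or wrong-version index file."""


class IndexParamsMismatch(ValueError):
    """Index was built with different parameters than the pipeline expects."""


@dataclass(frozen=True)
class IndexParams:
    lp: int = DEFAULT_LP
    format_version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.lp < 1:
            raise ValueError("lp must be >= 1")


@dataclass
class SingIndex:
    """In-memory index: parameters, GI, LI, and the database skeleton."""

    params: IndexParams
    gi: dict[PathFeature, dict[str, int]]
    li: dict[str, dict[PathFeature, int]]
    graph_order: list[str]
    n_vertices: dict[str, int] = field(default_factory=dict)

    def check_consistency(self) -> None:
        """Verify the GI/LI cross-consistency invariants; raise on violation.

        f in LI[g] iff g in GI[f], and GI[f][g] >= popcount(LI[g][f]) >= 1.
        """
        for f, per_graph in self.gi.items():
            for gid, count in per_graph.items():
                bits = self.li.get(gid, {}).get(f)
                if bits is None:
                    raise AssertionError(f"GI has ({f},{gid}) but LI does not")
                pc = bits.bit_count()
                if not count >= pc >= 1:
                    raise AssertionError(
                        f"count/popcount violation for ({f},{gid}): "
                        f"{count} < {pc} or empty start set"
                    )
        for gid, per_feature in self.li.items():
            for f in per_feature:
                if gid not in self.gi.get(f, {}):
                    raise AssertionError(f"LI has ({gid},{f}) but GI does not")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SingIndex):
            return NotImplemented
        return (
            self.params == other.params
            and self.gi == other.gi
            and self.li == other.li
            and self.graph_order == other.graph_order
            and self.n_vertices == other.n_vertices
        )


def build_index(db: GraphDB, params: IndexParams | None = None) -> SingIndex:
    """Build GI and LI by depth-first path enumeration over every graph.

    Deterministic for a given database and parameters.
    """
    params = params or IndexParams()
    gi: dict[PathFeature, dict[str, int]] = {}
    li: dict[str, dict[PathFeature, int]] = {}
    n_vertices: dict[str, int] = {}
    for g in db:
        counts, starts = graph_features(g, params.lp)
        li[g.graph_id] = starts
        n_vertices[g.graph_id] = g.n_vertices
        for f, c in counts.items():
            gi.setdefault(f, {})[g.graph_id] = c
    return SingIndex(
        params=params,
        gi=gi,
        li=li,
        graph_order=db.graph_ids,
        n_vertices=n_vertices,
    )


# -- serialization -------------------------------------------------------


def _pack_bits(bits: int, n: int) -> str:
    return base64.b64encode(bits.to_bytes((n + 7) // 8 or 1, "little")).decode()


def _unpack_bits(data: str) -> int:
    return int.from_bytes(base64.b64decode(data), "little")


def _payload(index: SingIndex) -> dict:
    features = sorted(index.gi)
    feat_pos = {f: i for i, f in enumerate(features)}
    gi_rows = [
        [[gid, index.gi[f][gid]] for gid in index.graph_order if gid in index.gi[f]]
        for f in features
    ]
    li_rows = []
    for gid in index.graph_order:
        n = index.n_vertices[gid]
        row = [
            [feat_pos[f], _pack_bits(bits, n)]
            for f, bits in sorted(index.li[gid].items())
        ]
        li_rows.append(row)
    return {
        "format": "sing-index",
        "version": index.params.format_version,
        "lp": index.params.lp,
        "graphs": [[gid, index.n_vertices[gid]] for gid in index.graph_order],
        "features": [list(f) for f in features],
        "gi": gi_rows,
        "li": li_rows,
    }


def save_index(index: SingIndex, sink: str | Path | BinaryIO) -> None:
    """Write the index as checksummed gzip JSON (canonical byte layout)."""
    payload = json.dumps(_payload(index), separators=(",", ":"), sort_keys=True)
    digest = hashlib.sha256(payload.encode()).hexdigest()
    envelope = json.dumps(
        {"payload": json.loads(payload), "sha256": digest},
        separators=(",", ":"),
        sort_keys=True,
    ).encode()
    if hasattr(sink, "write"):
        sink.write(gzip.compress(envelope, mtime=0))  # type: ignore[union-attr]
    else:
        Path(sink).write_bytes(gzip.compress(envelope, mtime=0))


def load_index(
    source: str | Path | BinaryIO, expect_lp: int | None = None
) -> SingIndex:
    """Load and validate an index file.

    Raises :class:`IndexFormatError` on corruption or version mismatch and
    :class:`IndexParamsMismatch` when ``expect_lp`` differs from the stored
    path bound.
    """
    if hasattr(source, "read"):
        raw = source.read()  # type: ignore[union-attr]
    else:
        raw = Path(source).read_bytes()
    try:
        envelope = json.loads(gzip.decompress(raw))
        payload = envelope["payload"]
        stored_digest = envelope["sha256"]
    except (OSError, ValueError, KeyError, EOFError) as exc:
        raise IndexFormatError(f"unreadable index file: {exc}") from exc
    canonical = json.dumps(payload, separators=(",", ":"), sort_keys=True)
    if hashlib.sha256(canonical.encode()).hexdigest() != stored_digest:
        raise IndexFormatError("checksum mismatch: index file is corrupt")
    if payload.get("format") != "sing-index":
        raise IndexFormatError("not a sing index file")
    if payload.get("version") != FORMAT_VERSION:
        raise IndexFormatError(
            f"unsupported index format version {payload.get('version')!r} "
            f"(expected {FORMAT_VERSION!r})"
        )
    lp = int(payload["lp"])
    if expect_lp is not None and lp != expect_lp:
        raise IndexParamsMismatch(
            f"index was built with lp={lp}, pipeline configured lp={expect_lp}"
        )
    features = [tuple(f) for f in payload["features"]]
    graph_order = [gid for gid, _n in payload["graphs"]]
    n_vertices = {gid: int(n) for gid, n in payload["graphs"]}
    gi: dict[PathFeature, dict[str, int]] = {
        f: {gid: int(c) for gid, c in row}
        for f, row in zip(features, payload["gi"])
    }
    li: dict[str, dict[PathFeature, int]] = {}
    for gid, row in zip(graph_order, payload["li"]):
        li[gid] = {features[pos]: _unpack_bits(b64) for pos, b64 in row}
    return SingIndex(
        params=IndexParams(lp=lp),
        gi=gi,
        li=li,
        graph_order=graph_order,
        n_vertices=n_vertices,
    )
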