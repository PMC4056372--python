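"""Sharded de Bruijn graph of canonical k-mers.

The graph stores one vertex per distinct canonical k-mer observed in the read
set, with its coverage depth (observations over both strands, saturating at
2**16 - 1), 4-bit edge marks per direction, and an optional interned color
set.  Edges are only ever marked when the corresponding adjacent window pair
was actually observed in an input sequence.

Vertices live in global arrays sorted by packed code; *shards* are index views
over that store, with membership decided by a pure function
``shard_of = splitmix64(code) % n_shards``.  Sharding is a logical contract —
a stand-in for a distributed hash table — and has no effect on any result.
No coverage floor is applied at build time: erroneous k-mers stay in the
graph and are filtered during traversal, not storage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

import numpy as np

from .kmers import (
    Kmer,
    _canonical_codes,
    _check_k,
    _codes_from_u8,
    _revcomp_code1,
    canonical_kmer,
    decode_code,
    encode_sequence,
)

__all__ = ["KmerVertex", "DeBruijnGraph", "build_graph"]

log = logging.getLogger(__name__)

COVERAGE_MAX = 2**16 - 1

_SEP = np.array([255], dtype=np.uint8)  # read separator; invalidates windows


def _splitmix64(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):  # uint64 wraparound is the point
        z = x + np.uint64(0x9E3779B97F4A7C15)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


def _or_reduce_by_gid(gids: np.ndarray, bits: np.ndarray, n: int) -> np.ndarray:
    """OR together `bits` grouped by vertex id; returns a length-n uint8 array."""
    out = np.zeros(n, dtype=np.uint8)
    if gids.size == 0:
        return out
    order = np.argsort(gids, kind="stable")
    g = gids[order]
    v = bits[order]
    starts = np.flatnonzero(np.concatenate(([True], g[1:] != g[:-1])))
    out[g[starts]] = np.bitwise_or.reduceat(v, starts)
    return out


@dataclass(frozen=True)
class KmerVertex:
    """A materialised view of one graph vertex."""

    kmer: Kmer
    coverage: int
    out_edges: int  # 4-bit mask over A,C,G,T extensions of the canonical strand
    in_edges: int  # 4-bit mask over A,C,G,T predecessors of the canonical strand
    colors: frozenset[int]


class DeBruijnGraph:
    """Canonical k-mer graph with coverage, read-observed edges and colors."""

    def __init__(self, k: int, n_shards: int = 4):
        _check_k(k)
        if n_shards < 1:
            raise ValueError("n_shards must be >= 1")
        self.k = k
        self.n_shards = n_shards
        self.codes = np.empty(0, dtype=np.uint64)
        self.coverage = np.empty(0, dtype=np.uint16)
        self.out_mask = np.empty(0, dtype=np.uint8)
        self.in_mask = np.empty(0, dtype=np.uint8)
        self.colorset_id = np.empty(0, dtype=np.int32)
        # interned color sets; id 0 could be any set, -1 means "no colors"
        self.colorsets: list[frozenset[int]] = []
        self._colorset_index: dict[frozenset[int], int] = {}
        self.shard_members: list[np.ndarray] = [
            np.empty(0, dtype=np.int64) for _ in range(n_shards)
        ]
        self.n_records = 0
        self.n_skipped_records = 0
        self.n_windows = 0
        self.n_saturated = 0

    # ------------------------------------------------------------------ build

    @classmethod
    def build(
        cls,
        reads: Iterable,
        k: int,
        n_shards: int = 4,
    ) -> "DeBruijnGraph":
        """Build the graph from a stream of sequences.

        ``reads`` may yield plain strings, ``(id, sequence)`` tuples or
        objects with a ``seq`` attribute.  Malformed records (empty or
        non-string sequences) are skipped and counted.  The result is
        deterministic and independent of read order and shard count.
        """
        g = cls(k, n_shards)
        chunks: list[np.ndarray] = []
        for rec in reads:
            seq = rec
            if isinstance(rec, tuple):
                seq = rec[1]
            elif hasattr(rec, "seq"):
                seq = str(rec.seq)
            if not isinstance(seq, str) or not seq:
                g.n_skipped_records += 1
                continue
            g.n_records += 1
            chunks.append(encode_sequence(seq))
            chunks.append(_SEP)
        if not chunks:
            return g
        enc = np.concatenate(chunks)
        codes, valid = _codes_from_u8(enc, k)
        canon, fwd = _canonical_codes(codes, k)

        vcodes = canon[valid]
        g.n_windows = int(vcodes.size)
        g.codes, counts = np.unique(vcodes, return_counts=True)
        g.n_saturated = int(np.count_nonzero(counts > COVERAGE_MAX))
        if g.n_saturated:
            log.warning("%d vertices saturated at coverage %d", g.n_saturated, COVERAGE_MAX)
        g.coverage = np.minimum(counts, COVERAGE_MAX).astype(np.uint16)
        n = g.codes.size
        g.colorset_id = np.full(n, -1, dtype=np.int32)

        # adjacent valid window pairs (never spans two reads: the separator
        # invalidates every window that touches it)
        adj = np.flatnonzero(valid[:-1] & valid[1:])
        if adj.size:
            u_gid = np.searchsorted(g.codes, canon[adj]).astype(np.int64)
            v_gid = np.searchsorted(g.codes, canon[adj + 1]).astype(np.int64)
            b = enc[adj + k].astype(np.uint8)  # base appended on the read strand
            a = enc[adj].astype(np.uint8)  # base dropped on the read strand
            u_fwd = fwd[adj]
            v_fwd = fwd[adj + 1]
            # prefix vertex: forward window -> out edge b; else in edge comp(b)
            out_g = np.concatenate([u_gid[u_fwd], v_gid[~v_fwd]])
            out_b = np.concatenate([b[u_fwd], (3 - a[~v_fwd])])
            in_g = np.concatenate([v_gid[v_fwd], u_gid[~u_fwd]])
            in_b = np.concatenate([a[v_fwd], (3 - b[~u_fwd])])
            g.out_mask = _or_reduce_by_gid(out_g, np.left_shift(1, out_b).astype(np.uint8), n)
            g.in_mask = _or_reduce_by_gid(in_g, np.left_shift(1, in_b).astype(np.uint8), n)
        else:
            g.out_mask = np.zeros(n, dtype=np.uint8)
            g.in_mask = np.zeros(n, dtype=np.uint8)

        shard = (_splitmix64(g.codes) % np.uint64(n_shards)).astype(np.int64)
        g.shard_members = [np.flatnonzero(shard == s) for s in range(n_shards)]
        return g

    # ----------------------------------------------------------------- access

    def __len__(self) -> int:
        return int(self.codes.size)

    @staticmethod
    def shard_of(code: int, n_shards: int) -> int:
        """Pure shard assignment for a packed canonical code."""
        return int(_splitmix64(np.uint64(code)) % np.uint64(n_shards))

    def lookup(self, canon_codes: np.ndarray) -> np.ndarray:
        """Vectorised vertex lookup; returns -1 for absent k-mers."""
        if self.codes.size == 0:
            return np.full(canon_codes.shape, -1, dtype=np.int64)
        pos = np.searchsorted(self.codes, canon_codes)
        pos_c = np.minimum(pos, self.codes.size - 1)
        hit = self.codes[pos_c] == canon_codes
        return np.where(hit, pos_c, -1).astype(np.int64)

    def gid_of(self, kmer: Kmer | str) -> int:
        if isinstance(kmer, str):
            kmer, _ = canonical_kmer(kmer)
        kmer = kmer.canonical()
        gid = int(self.lookup(np.array([kmer.code], dtype=np.uint64))[0])
        return gid

    def colors_of(self, gid: int) -> frozenset[int]:
        sid = int(self.colorset_id[gid])
        return self.colorsets[sid] if sid >= 0 else frozenset()

    def vertex(self, kmer: Kmer | str) -> KmerVertex:
        gid = self.gid_of(kmer)
        if gid < 0:
            raise KeyError(f"k-mer not present in graph: {kmer}")
        return KmerVertex(
            kmer=Kmer(int(self.codes[gid]), self.k),
            coverage=int(self.coverage[gid]),
            out_edges=int(self.out_mask[gid]),
            in_edges=int(self.in_mask[gid]),
            colors=self.colors_of(gid),
        )

    def neighbors(self, kmer: Kmer | str, direction: str = "forward") -> list[tuple[str, Kmer]]:
        """Marked-edge neighbors of a canonical vertex that resolve to stored vertices.

        ``forward`` follows out-edges of the canonical orientation; ``reverse``
        follows in-edges.  Raises ``KeyError`` for an absent k-mer.
        """
        gid = self.gid_of(kmer)
        if gid < 0:
            raise KeyError(f"k-mer not present in graph: {kmer}")
        k = self.k
        code = int(self.codes[gid])
        out: list[tuple[str, Kmer]] = []
        if direction == "forward":
            mask = int(self.out_mask[gid])
            for b in range(4):
                if mask & (1 << b):
                    nxt = ((code << 2) & ((1 << (2 * k)) - 1)) | b
                    canon = min(nxt, _revcomp_code1(nxt, k))
                    if self.lookup(np.array([canon], dtype=np.uint64))[0] >= 0:
                        out.append(("ACGT"[b], Kmer(canon, k)))
        elif direction == "reverse":
            mask = int(self.in_mask[gid])
            for b in range(4):
                if mask & (1 << b):
                    nxt = (code >> 2) | (b << (2 * (k - 1)))
                    canon = min(nxt, _revcomp_code1(nxt, k))
                    if self.lookup(np.array([canon], dtype=np.uint64))[0] >= 0:
                        out.append(("ACGT"[b], Kmer(canon, k)))
        else:
            raise ValueError("direction must be 'forward' or 'reverse'")
        return out

    def coverage_histogram(self) -> dict[int, int]:
        """Diagnostic coverage histogram.

        This is reporting output only: no assembly decision consumes it (the
        assembler works from per-seed local statistics exclusively).
        """
        vals, counts = np.unique(self.coverage, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    # ----------------------------------------------------------------- colors

    def intern_colorset(self, colors: frozenset[int]) -> int:
        sid = self._colorset_index.get(colors)
        if sid is None:
            sid = len(self.colorsets)
            self.colorsets.append(colors)
            self._colorset_index[colors] = sid
        return sid

    def add_color(self, gids: np.ndarray, color: int) -> None:
        """Add one color to the given vertices (interned, idempotent)."""
        if len(gids) == 0:
            return
        gids = np.asarray(gids, dtype=np.int64)
        old_sids = self.colorset_id[gids]
        # map each distinct old set id to the id of (old set | {color})
        for old in np.unique(old_sids):
            old = int(old)
            base = self.colorsets[old] if old >= 0 else frozenset()
            if color in base:
                continue
            new = self.intern_colorset(base | {color})
            sel = gids[old_sids == old]
            self.colorset_id[sel] = new

    # ------------------------------------------------------------- invariants

    def check_shards(self) -> bool:
        """Full-scan check that every vertex sits in its shard_of shard."""
        seen = 0
        for s, members in enumerate(self.shard_members):
            sh = _splitmix64(self.codes[members]) % np.uint64(self.n_shards)
            if not np.all(sh == s):
                return False
            seen += members.size
        return seen == len(self)

    # -------------------------------------------------------------- serialise

    def serialize(self, fh: IO[str]) -> None:
        """Flat TSV dump (kmer, coverage, out-mask, in-mask, color-list).

        Rows are sorted by k-mer word, so the serialisation is byte-identical
        for any read order or shard count that produced the same graph.
        """
        fh.write("#kmer\tcoverage\tout\tin\tcolors\n")
        for gid in range(len(self)):
            colors = self.colors_of(gid)
            cstr = ",".join(str(c) for c in sorted(colors)) if colors else "-"
            fh.write(
                f"{decode_code(int(self.codes[gid]), self.k)}\t"
                f"{int(self.coverage[gid])}\t{int(self.out_mask[gid])}\t"
                f"{int(self.in_mask[gid])}\t{cstr}\n"
            )

    def vertices(self) -> Iterator[KmerVertex]:
        for gid in range(len(self)):
            yield KmerVertex(
                kmer=Kmer(int(self.codes[gid]), self.k),
                coverage=int(self.coverage[gid]),
                out_edges=int(self.out_mask[gid]),
                in_edges=int(self.in_mask[gid]),
                colors=self.colors_of(gid),
            )


def build_graph(reads: Iterable, k: int, n_shards: int = 4) -> DeBruijnGraph:
    """Functional alias for :meth:`DeBruijnGraph.build`."""
    return DeBruijnGraph.build(reads, k, n_shards=n_shards)
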