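"""Seed-and-extend assembly guided by local coverage and read markers.

The assembler never simplifies the graph and never consults any global
coverage statistic.  It proceeds in stages:

1. *Seeds*: maximal unitig-like paths whose internal vertices have exactly
   one "present" predecessor and successor, where presence means coverage at
   least ``cov_present`` (default 2).  Seeds shorter than ``2k - 1`` nt are
   discarded.
2. *Local statistics*: the modal and minimum coverage of each seed are
   computed from the seed's own vertices only.
3. *Read markers*: each read is anchored to a seed at its first k-mer that
   lies on the seed and whose coverage is at most ``3 x mode`` (repeat
   avoidance); one marker per read per seed.
4. *Extension*: each seed is extended in both directions.  At a step with
   more than one candidate successor — or whose sole candidate is below the
   presence floor — anchored reads laid along the path vote for the base
   they read at the decision position; mates projected at the estimated
   insert length are consulted when read votes are inconclusive.  The top
   candidate is taken only with at least ``vote_min`` votes and at least
   ``vote_ratio`` times the runner-up; otherwise extension stops
   ("ambiguous").  Re-entering the current path stops with "cycle"; walking
   onto a vertex claimed by a previously emitted contig stops with
   "conflict".
5. *Output*: contigs are emitted in canonical orientation, deduplicated,
   filtered at 100 nt, and linked into scaffolds by read pairs (at least 3
   concordant pairs per junction).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .graph import DeBruijnGraph
from .io import ReadSet
from .kmers import (
    _canonical_codes,
    _codes_from_u8,
    _revcomp_code1,
    decode_code,
    encode_sequence,
    revcomp,
)

__all__ = [
    "AssemblyParams",
    "SeedStats",
    "ReadMarker",
    "ContigPath",
    "AssemblyContext",
    "AssemblyResult",
    "find_seeds",
    "seed_local_coverage",
    "select_read_markers",
    "estimate_insert_size",
    "extend_path",
    "scaffold",
    "assemble",
    "assemble_graph",
]

log = logging.getLogger(__name__)

_BASE = "ACGT"


@dataclass(frozen=True)
class AssemblyParams:
    """Traversal constants; conservative defaults favour correctness."""

    k: int = 31
    n_shards: int = 4
    cov_present: int = 2  # coverage floor for a vertex to count as present
    repeat_mult: float = 3.0  # marker repeat cutoff = repeat_mult * seed mode
    vote_min: int = 2
    vote_ratio: float = 2.0
    min_seed_nt: int | None = None  # None -> 2k - 1
    min_contig_nt: int = 100
    scaffold_min_links: int = 3
    insert_prior: tuple[float, float] = (400.0, 40.0)
    insert_min_pairs: int = 30

    @property
    def seed_floor(self) -> int:
        return 2 * self.k - 1 if self.min_seed_nt is None else self.min_seed_nt


@dataclass
class SeedStats:
    """Per-seed local coverage summary; nothing global is ever used."""

    mode: int
    minimum: int
    coverages: np.ndarray


@dataclass(frozen=True)
class ReadMarker:
    """Anchors one read on one seed path at a specific k-mer."""

    read: int
    seed: int
    path_offset: int
    forward: bool  # read runs along the seed's stored orientation
    read_offset: int


@dataclass
class ContigPath:
    """An ordered walk in the graph plus its nucleotide sequence."""

    codes: np.ndarray  # canonical k-mer codes along the walk
    strands: np.ndarray  # True where walk orientation == canonical orientation
    gids: np.ndarray
    sequence: str
    seed_id: int = -1
    left_stop: str = "no-successor"
    right_stop: str = "no-successor"

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def nt(self) -> int:
        return len(self.sequence)


# --------------------------------------------------------------------- seeds


def _neighbor_tables(graph: DeBruijnGraph, cov_present: int):
    """Vectorised per-vertex degree/neighbor info among *present* vertices.

    For each vertex and each side (A = canonical-out, B = canonical-in)
    returns the number of present neighbors, the single neighbor gid when the
    degree is 1, and whether the step enters the neighbor through its B side
    (i.e. continues along the neighbor's canonical orientation).
    """
    k = graph.k
    n = len(graph)
    codes = graph.codes
    present = graph.coverage >= cov_present
    maskK = np.uint64((1 << (2 * k)) - 1)

    deg = np.zeros((2, n), dtype=np.int8)
    nbr = np.full((2, n), -1, dtype=np.int64)
    nbr_entry_b = np.zeros((2, n), dtype=bool)

    for side in (0, 1):  # 0 = A (out), 1 = B (in)
        mask = graph.out_mask if side == 0 else graph.in_mask
        for b in range(4):
            has = (mask >> np.uint8(b)) & np.uint8(1)
            if side == 0:
                # oriented next word: suffix + b
                word = ((codes << np.uint64(2)) & maskK) | np.uint64(b)
            else:
                # walking in reverse orientation: rc(b . prefix)
                raw = (codes >> np.uint64(2)) | (np.uint64(b) << np.uint64(2 * (k - 1)))
                word = _rc_vec(raw, k)
            canon, fwd = _canonical_codes(word, k)
            gid = graph.lookup(canon)
            ok = (has > 0) & (gid >= 0)
            ok[ok] &= present[gid[ok]]
            deg[side] += ok
            nbr[side][ok] = gid[ok]
            nbr_entry_b[side][ok] = fwd[ok]
    return present, deg, nbr, nbr_entry_b


def _rc_vec(codes: np.ndarray, k: int) -> np.ndarray:
    from .kmers import _revcomp_codes

    return _revcomp_codes(codes, k)


def find_seeds(
    graph: DeBruijnGraph,
    min_seed_nt: int | None = None,
    cov_present: int = 2,
    k_override: int | None = None,
) -> list[ContigPath]:
    """Maximal single-path chains of present vertices, canonically oriented.

    Seeds are vertex-disjoint and returned sorted by canonical sequence, so
    the output is deterministic and strand-symmetric.
    """
    k = graph.k if k_override is None else k_override
    floor = 2 * k - 1 if min_seed_nt is None else min_seed_nt
    n = len(graph)
    if n == 0:
        return []
    present, deg, nbr, entry_b = _neighbor_tables(graph, cov_present)

    def step(gid: int, orient: int):
        """One chain step leaving `gid` in walk orientation `orient` (+1/-1)."""
        side = 0 if orient > 0 else 1
        if deg[side][gid] != 1:
            return None
        v = int(nbr[side][gid])
        v_orient = 1 if entry_b[side][gid] else -1
        v_entry_side = 1 if v_orient > 0 else 0
        if deg[v_entry_side][v] != 1:
            return None
        return v, v_orient

    visited = ~present.copy()
    seeds: list[ContigPath] = []
    for start in range(n):
        if visited[start]:
            continue
        # walk left to the chain start (or once around a cycle)
        gid, orient = start, 1
        while True:
            back = step(gid, -orient)
            if back is None:
                break
            pgid, porient = back
            if pgid == start or visited[pgid]:
                break  # cycle: break deterministically at the scan vertex
            gid, orient = pgid, -porient
        # walk right, collecting
        chain_g = [gid]
        chain_o = [orient]
        visited[gid] = True
        while True:
            nxt = step(chain_g[-1], chain_o[-1])
            if nxt is None:
                break
            vgid, vorient = nxt
            if visited[vgid]:
                break
            chain_g.append(vgid)
            chain_o.append(vorient)
            visited[vgid] = True
        nt = len(chain_g) + k - 1
        if nt < floor:
            continue
        gids = np.array(chain_g, dtype=np.int64)
        strands = np.array([o > 0 for o in chain_o], dtype=bool)
        codes = graph.codes[gids]
        seq = _walk_sequence(codes, strands, k)
        seeds.append(_orient_canonical(ContigPath(codes, strands, gids, seq)))
    seeds.sort(key=lambda s: s.sequence)
    for i, s in enumerate(seeds):
        s.seed_id = i
    return seeds


def _walk_sequence(codes: np.ndarray, strands: np.ndarray, k: int) -> str:
    words = np.where(strands, codes, _rc_vec(codes, k))
    first = decode_code(int(words[0]), k)
    tail = "".join(_BASE[int(w) & 3] for w in words[1:])
    return first + tail


def _orient_canonical(path: ContigPath) -> ContigPath:
    rc = revcomp(path.sequence)
    if rc < path.sequence:
        return ContigPath(
            codes=path.codes[::-1].copy(),
            strands=~path.strands[::-1],
            gids=path.gids[::-1].copy(),
            sequence=rc,
            seed_id=path.seed_id,
            left_stop=path.right_stop,
            right_stop=path.left_stop,
        )
    return path


def seed_local_coverage(seed: ContigPath, graph: DeBruijnGraph) -> SeedStats:
    """Mode and minimum coverage sampled from the seed path only.

    The mode breaks ties toward the smaller coverage value.
    """
    covs = graph.coverage[seed.gids].astype(np.int64)
    vals, counts = np.unique(covs, return_counts=True)
    return SeedStats(
        mode=int(vals[np.argmax(counts)]),
        minimum=int(vals[0]),
        coverages=covs,
    )


# ------------------------------------------------------------------- context


@dataclass
class AssemblyContext:
    """Everything extension needs, shared across seeds."""

    graph: DeBruijnGraph
    params: AssemblyParams
    reads: ReadSet
    seeds: list[ContigPath]
    stats: list[SeedStats]
    vertex_seed: np.ndarray  # gid -> seed id (-1 off-seed)
    vertex_pos: np.ndarray  # gid -> offset on its seed
    markers_at: dict[tuple[int, int], list[ReadMarker]]
    insert_mean: float
    insert_sd: float
    insert_n: int
    claimed: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    read_bytes: list[bytes] = field(default_factory=list)
    max_read_len: int = 0

    @classmethod
    def prepare(
        cls, graph: DeBruijnGraph, reads: ReadSet, params: AssemblyParams
    ) -> "AssemblyContext":
        seeds = find_seeds(graph, params.seed_floor, params.cov_present)
        stats = [seed_local_coverage(s, graph) for s in seeds]
        vertex_seed = np.full(len(graph), -1, dtype=np.int64)
        vertex_pos = np.zeros(len(graph), dtype=np.int64)
        for s in seeds:
            vertex_seed[s.gids] = s.seed_id
            vertex_pos[s.gids] = np.arange(len(s))
        markers = _bulk_markers(graph, reads, seeds, stats, vertex_seed, vertex_pos, params)
        markers_at: dict[tuple[int, int], list[ReadMarker]] = {}
        for m in markers:
            markers_at.setdefault((m.seed, m.path_offset), []).append(m)
        mean, sd, n_used = estimate_insert_size(reads, markers, params)
        ctx = cls(
            graph=graph,
            params=params,
            reads=reads,
            seeds=seeds,
            stats=stats,
            vertex_seed=vertex_seed,
            vertex_pos=vertex_pos,
            markers_at=markers_at,
            insert_mean=mean,
            insert_sd=sd,
            insert_n=n_used,
        )
        ctx.claimed = np.zeros(len(graph), dtype=bool)
        ctx.read_bytes = [s.encode() for s in reads.seqs]
        ctx.max_read_len = max((len(s) for s in reads.seqs), default=0)
        return ctx


def _read_window_table(reads: ReadSet, k: int):
    """Window table over all reads: per window (read, offset, canon, fwd)."""
    enc_parts = []
    bounds = [0]
    for s in reads.seqs:
        enc_parts.append(encode_sequence(s))
        enc_parts.append(np.array([255], dtype=np.uint8))
        bounds.append(bounds[-1] + len(s) + 1)
    if not enc_parts:
        return (np.empty(0, np.int64),) * 2 + (np.empty(0, np.uint64), np.empty(0, bool))
    enc = np.concatenate(enc_parts)
    codes, valid = _codes_from_u8(enc, k)
    canon, fwd = _canonical_codes(codes, k)
    idx = np.flatnonzero(valid)
    starts = np.array(bounds[:-1], dtype=np.int64)
    read_of = np.searchsorted(starts, idx, side="right") - 1
    offset = idx - starts[read_of]
    return read_of, offset, canon[idx], fwd[idx]


def _bulk_markers(
    graph: DeBruijnGraph,
    reads: ReadSet,
    seeds: list[ContigPath],
    stats: list[SeedStats],
    vertex_seed: np.ndarray,
    vertex_pos: np.ndarray,
    params: AssemblyParams,
) -> list[ReadMarker]:
    if not seeds or len(reads) == 0:
        return []
    read_of, offset, canon, fwd = _read_window_table(reads, graph.k)
    gid = graph.lookup(canon)
    on = gid >= 0
    on[on] &= vertex_seed[gid[on]] >= 0
    if not on.any():
        return []
    read_of, offset, fwd, gid = read_of[on], offset[on], fwd[on], gid[on]
    sid = vertex_seed[gid]
    cov = graph.coverage[gid].astype(np.int64)
    modes = np.array([st.mode for st in stats], dtype=np.int64)
    mins = np.array([st.minimum for st in stats], dtype=np.int64)
    ok = (cov >= mins[sid]) & (cov <= params.repeat_mult * modes[sid])
    read_of, offset, fwd, gid, sid = (
        a[ok] for a in (read_of, offset, fwd, gid, sid)
    )
    if read_of.size == 0:
        return []
    # first qualifying window per (read, seed): stable sort then unique
    order = np.lexsort((offset, sid, read_of))
    r_s = np.stack([read_of[order], sid[order]], axis=1)
    first = np.flatnonzero(
        np.concatenate(([True], np.any(r_s[1:] != r_s[:-1], axis=1)))
    )
    sel = order[first]
    # seed strand at the anchoring vertex
    seed_strand = np.zeros(len(graph.codes), dtype=bool)
    for s in seeds:
        seed_strand[s.gids] = s.strands
    return [
        ReadMarker(
            read=int(read_of[i]),
            seed=int(sid[i]),
            path_offset=int(vertex_pos[gid[i]]),
            forward=bool(fwd[i] == seed_strand[gid[i]]),
            read_offset=int(offset[i]),
        )
        for i in sel
    ]


def select_read_markers(
    reads: ReadSet,
    seed: ContigPath,
    stats: SeedStats,
    graph: DeBruijnGraph,
    params: AssemblyParams | None = None,
) -> list[ReadMarker]:
    """Markers of all reads against a single seed (one marker per read)."""
    params = params or AssemblyParams(k=graph.k)
    sid = max(seed.seed_id, 0)
    vertex_seed = np.full(len(graph), -1, dtype=np.int64)
    vertex_pos = np.zeros(len(graph), dtype=np.int64)
    vertex_seed[seed.gids] = sid
    vertex_pos[seed.gids] = np.arange(len(seed))
    # pad the per-seed lists so that index `sid` resolves to this seed
    return _bulk_markers(
        graph, reads, [seed] * (sid + 1), [stats] * (sid + 1), vertex_seed, vertex_pos, params
    )


def estimate_insert_size(
    reads: ReadSet, markers: Sequence[ReadMarker], params: AssemblyParams
) -> tuple[float, float, int]:
    """Mean/sd of outer fragment length over pairs co-anchored on one seed.

    The top and bottom 5% of outer distances are discarded as outliers.
    Falls back to the configured prior when fewer than ``insert_min_pairs``
    usable pairs exist.
    """
    k = params.k
    by_read: dict[int, ReadMarker] = {}
    for m in markers:
        by_read.setdefault(m.read, m)
    outers = []
    for r, m in by_read.items():
        mt = int(reads.mate[r]) if r < len(reads.mate) else -1
        if mt < 0 or mt <= r:
            continue
        mm = by_read.get(mt)
        if mm is None or mm.seed != m.seed:
            continue
        spans = []
        for mk, length in ((m, len(reads.seqs[r])), (mm, len(reads.seqs[mt]))):
            start = (
                mk.path_offset - mk.read_offset
                if mk.forward
                else mk.path_offset - (length - k - mk.read_offset)
            )
            spans.append((start, start + length))
        outer = max(s[1] for s in spans) - min(s[0] for s in spans)
        outers.append(outer)
    if len(outers) < params.insert_min_pairs:
        log.warning(
            "only %d co-anchored pairs; falling back to insert prior %s",
            len(outers),
            params.insert_prior,
        )
        return params.insert_prior[0], params.insert_prior[1], 0
    arr = np.sort(np.array(outers, dtype=float))
    lo = int(np.floor(0.05 * arr.size))
    hi = arr.size - lo
    trimmed = arr[lo:hi]
    return float(trimmed.mean()), float(trimmed.std()), int(trimmed.size)


# ----------------------------------------------------------------- extension


class _Walk:
    """Mutable extension state: oriented walk plus anchored voting reads."""

    __slots__ = (
        "gids",
        "codes",
        "strands",
        "seq",
        "gid_set",
        "active",
        "anchored",
    )

    def __init__(self):
        self.gids: list[int] = []
        self.codes: list[int] = []
        self.strands: list[bool] = []
        self.seq = bytearray()
        self.gid_set: set[int] = set()
        # active voting reads: [oriented seq bytes, start base pos, read idx, raw_forward]
        self.active: list[tuple[bytes, int, int, bool]] = []
        self.anchored: set[int] = set()


def _anchor_at(ctx: AssemblyContext, walk: _Walk, t: int) -> None:
    """Anchor markers of the vertex at walk position t onto the walk."""
    gid = walk.gids[t]
    sid = int(ctx.vertex_seed[gid])
    if sid < 0:
        return
    pos = int(ctx.vertex_pos[gid])
    mlist = ctx.markers_at.get((sid, pos))
    if not mlist:
        return
    seed = ctx.seeds[sid]
    traverse_fwd = walk.strands[t] == bool(seed.strands[pos])
    k = ctx.params.k
    for m in mlist:
        if m.read in walk.anchored:
            continue
        raw = ctx.read_bytes[m.read]
        along = m.forward == traverse_fwd
        if along:
            seq = raw
            ro = m.read_offset
        else:
            seq = revcomp(raw.decode()).encode()
            ro = len(raw) - k - m.read_offset
        walk.active.append((seq, t - ro, m.read, along))
        walk.anchored.add(m.read)


def _prune_active(walk: _Walk, pos: int) -> None:
    if len(walk.active) > 256:
        walk.active = [a for a in walk.active if a[1] + len(a[0]) > pos]


def _candidates(ctx: AssemblyContext, walk: _Walk):
    """Successor candidates of the walk end: (base, word, canon, strand, gid, cov)."""
    k = ctx.params.k
    maskK = (1 << (2 * k)) - 1
    code = walk.codes[-1]
    strand = walk.strands[-1]
    g = ctx.graph
    gid = walk.gids[-1]
    mask = int(g.out_mask[gid]) if strand else int(g.in_mask[gid])
    word = code if strand else _revcomp_code1(code, k)
    out = []
    for b in range(4):
        if not (mask >> b) & 1:
            continue
        nb = b if strand else 3 - b
        w2 = ((word << 2) & maskK) | nb
        rc2 = _revcomp_code1(w2, k)
        if w2 <= rc2:
            canon2, s2 = w2, True
        else:
            canon2, s2 = rc2, False
        # note: search with a uint64 scalar — a python int would be promoted
        # to float64 and lose low bits of the 62-bit code
        gid2 = int(np.searchsorted(g.codes, np.uint64(canon2)))
        if gid2 >= len(g.codes) or int(g.codes[gid2]) != canon2:
            continue
        out.append((nb, w2, canon2, s2, gid2, int(g.coverage[gid2])))
    return out


def _read_votes(walk: _Walk, pos: int) -> Counter:
    votes: Counter = Counter()
    enc = {65: 0, 67: 1, 71: 2, 84: 3}
    for seq, start, _r, _fw in walk.active:
        idx = pos - start
        if 0 <= idx < len(seq):
            b = enc.get(seq[idx])
            if b is not None:
                votes[b] += 1
    return votes


def _mate_votes(ctx: AssemblyContext, walk: _Walk, pos: int) -> Counter:
    """Votes from projected mates of on-path reads near the decision position."""
    votes: Counter = Counter()
    mu = ctx.insert_mean
    sd = ctx.insert_sd
    enc = {65: 0, 67: 1, 71: 2, 84: 3}
    for seq, start, r, raw_fwd in walk.active:
        if not raw_fwd:
            continue  # mate lies leftward; irrelevant for rightward extension
        if r >= len(ctx.reads.mate):
            continue
        mt = int(ctx.reads.mate[r])
        if mt < 0 or mt in walk.anchored:
            continue
        mseq = ctx.read_bytes[mt]
        L = len(mseq)
        d = pos - start  # implied insert window: d < insert <= d + L
        if d + L < mu - 3 * sd or d >= mu + 3 * sd:
            continue
        idx = pos - (start + int(round(mu)) - L)
        if 0 <= idx < L:
            oriented = revcomp(mseq.decode()).encode()
            b = enc.get(oriented[idx])
            if b is not None:
                votes[b] += 1
    return votes


def _decide(ctx: AssemblyContext, walk: _Walk, cands):
    """Pick a successor or return a stop reason.

    Present candidates are preferred; a single present candidate is taken
    outright.  Any other situation (a branch, or a sole sub-floor candidate)
    must win the vote: >= vote_min read votes and >= vote_ratio times the
    runner-up, with mate votes added only when read votes are inconclusive.
    """
    p = ctx.params
    if not cands:
        return None, "no-successor"
    present = [c for c in cands if c[5] >= p.cov_present]
    pool = present if present else cands
    if len(pool) == 1 and present:
        return pool[0], None
    pos = len(walk.seq)  # decision base position

    def winner(votes: Counter):
        scored = sorted(pool, key=lambda c: (-votes.get(c[0], 0), c[0]))
        top_v = votes.get(scored[0][0], 0)
        runner_v = votes.get(scored[1][0], 0) if len(scored) > 1 else 0
        if top_v >= p.vote_min and top_v >= p.vote_ratio * runner_v:
            return scored[0]
        return None

    votes = _read_votes(walk, pos)
    choice = winner(votes)
    if choice is None:
        votes = votes + _mate_votes(ctx, walk, pos)
        choice = winner(votes)
    if choice is None:
        return None, "ambiguous"
    return choice, None


def _extend_right(ctx: AssemblyContext, walk: _Walk) -> str:
    append = walk.seq.append
    while True:
        cands = _candidates(ctx, walk)
        choice, reason = _decide(ctx, walk, cands)
        if choice is None:
            return reason
        nb, _w2, canon2, s2, gid2, _cov = choice
        if gid2 in walk.gid_set:
            return "cycle"
        if ctx.claimed[gid2]:
            return "conflict"
        walk.gids.append(gid2)
        walk.codes.append(canon2)
        walk.strands.append(s2)
        walk.gid_set.add(gid2)
        append(ord(_BASE[nb]))
        _anchor_at(ctx, walk, len(walk.gids) - 1)
        if len(walk.gids) % 512 == 0:
            _prune_active(walk, len(walk.seq) - ctx.max_read_len - 1)


def _flip_walk(ctx: AssemblyContext, walk: _Walk) -> _Walk:
    out = _Walk()
    out.gids = walk.gids[::-1]
    out.codes = walk.codes[::-1]
    out.strands = [not s for s in walk.strands[::-1]]
    out.seq = bytearray(revcomp(walk.seq.decode()).encode())
    out.gid_set = set(out.gids)
    span = ctx.max_read_len + 2
    for t in range(max(0, len(out.gids) - span), len(out.gids)):
        _anchor_at(ctx, out, t)
    return out


def extend_path(ctx: AssemblyContext, seed: ContigPath) -> ContigPath:
    """Extend one seed in both directions; returns the canonical contig."""
    walk = _Walk()
    walk.gids = [int(g) for g in seed.gids]
    walk.codes = [int(c) for c in seed.codes]
    walk.strands = [bool(s) for s in seed.strands]
    walk.seq = bytearray(seed.sequence.encode())
    walk.gid_set = set(walk.gids)
    span = ctx.max_read_len + 2
    for t in range(max(0, len(walk.gids) - span), len(walk.gids)):
        _anchor_at(ctx, walk, t)
    right_stop = _extend_right(ctx, walk)
    walk = _flip_walk(ctx, walk)
    left_stop = _extend_right(ctx, walk)
    # walk is now in flipped orientation: its sequence is the reverse
    # complement of the extended contig read left-to-right
    path = ContigPath(
        codes=np.array(walk.codes, dtype=np.uint64),
        strands=np.array(walk.strands, dtype=bool),
        gids=np.array(walk.gids, dtype=np.int64),
        sequence=walk.seq.decode(),
        seed_id=seed.seed_id,
        left_stop=right_stop,
        right_stop=left_stop,
    )
    return _orient_canonical(path)


# ------------------------------------------------------------------ assembly


@dataclass
class AssemblyResult:
    contigs: list[tuple[str, str]]
    scaffolds: list[tuple[str, str]]
    paths: list[ContigPath]
    report: dict


def _normalize_reads(reads) -> ReadSet:
    if isinstance(reads, ReadSet):
        return reads
    ids, seqs = [], []
    for i, rec in enumerate(reads):
        if isinstance(rec, tuple):
            ids.append(str(rec[0]))
            seqs.append(rec[1])
        else:
            ids.append(f"r{i}")
            seqs.append(str(rec))
    rs = ReadSet(ids=ids, seqs=seqs)
    # infer mate pairing from /1,/2 suffixes
    index = {rid: i for i, rid in enumerate(ids)}
    for i, rid in enumerate(ids):
        if rid.endswith("/1") and rid[:-2] + "/2" in index:
            j = index[rid[:-2] + "/2"]
            rs.mate[i] = j
            rs.mate[j] = i
    return rs


def assemble(reads, k: int = 31, params: AssemblyParams | None = None) -> AssemblyResult:
    """Full pipeline: build graph, seed, mark, extend, deduplicate, scaffold."""
    params = params or AssemblyParams(k=k)
    if params.k != k:
        params = AssemblyParams(**{**params.__dict__, "k": k})
    rs = _normalize_reads(reads)
    graph = DeBruijnGraph.build(list(rs), k, n_shards=params.n_shards)
    return assemble_graph(graph, rs, params)


def assemble_graph(
    graph: DeBruijnGraph, reads, params: AssemblyParams | None = None
) -> AssemblyResult:
    """Assemble an already-built graph.

    Colors on the graph are ignored entirely: assembly is independent of
    coloring, so a colored and an uncolored graph of the same reads yield
    byte-identical output.
    """
    params = params or AssemblyParams(k=graph.k)
    rs = _normalize_reads(reads)
    if len(graph) == 0:
        log.warning("no usable k-mers in input; empty assembly")
        return AssemblyResult([], [], [], {"n_reads": len(rs), "n_seeds": 0, "stop_reasons": {}})
    ctx = AssemblyContext.prepare(graph, rs, params)
    order = sorted(range(len(ctx.seeds)), key=lambda i: (-len(ctx.seeds[i]), ctx.seeds[i].sequence))
    paths: list[ContigPath] = []
    stop_reasons: Counter = Counter()
    n_skipped = 0
    for sidx in order:
        seed = ctx.seeds[sidx]
        if ctx.claimed[seed.gids].all():
            n_skipped += 1
            continue
        path = extend_path(ctx, seed)
        ctx.claimed[path.gids] = True
        stop_reasons[path.left_stop] += 1
        stop_reasons[path.right_stop] += 1
        paths.append(path)
    # deduplicate identical canonical sequences
    seen: dict[str, ContigPath] = {}
    for p in paths:
        if p.sequence not in seen:
            seen[p.sequence] = p
    unique_paths = sorted(seen.values(), key=lambda p: (-p.nt, p.sequence))
    out_paths = [p for p in unique_paths if p.nt >= params.min_contig_nt]
    contigs = [(f"contig_{i + 1:05d}", p.sequence) for i, p in enumerate(out_paths)]
    scaffolds = scaffold(out_paths, ctx, contig_names=[c[0] for c in contigs])
    report = {
        "n_reads": len(rs),
        "n_seeds": len(ctx.seeds),
        "n_seeds_skipped_claimed": n_skipped,
        "stop_reasons": dict(stop_reasons),
        "insert_mean": ctx.insert_mean,
        "insert_sd": ctx.insert_sd,
        "insert_pairs_used": ctx.insert_n,
        "n_contigs_all": len(unique_paths),
        "n_contigs": len(contigs),
        "total_contig_nt": sum(p.nt for p in out_paths),
        "n_scaffolds": len(scaffolds),
    }
    return AssemblyResult(contigs=contigs, scaffolds=scaffolds, paths=out_paths, report=report)


# ----------------------------------------------------------------- scaffolds


def _contig_read_anchors(ctx: AssemblyContext, paths: list[ContigPath]):
    """First-window anchor of every read on the final contigs.

    Returns dict read -> (contig idx, start in contig-forward coords,
    aligned_forward).
    """
    n = len(ctx.graph)
    contig_of = np.full(n, -1, dtype=np.int64)
    pos_of = np.zeros(n, dtype=np.int64)
    strand_of = np.zeros(n, dtype=bool)
    for ci, p in enumerate(paths):
        contig_of[p.gids] = ci
        pos_of[p.gids] = np.arange(len(p))
        strand_of[p.gids] = p.strands
    read_of, offset, canon, fwd = _read_window_table(ctx.reads, ctx.params.k)
    gid = ctx.graph.lookup(canon)
    on = gid >= 0
    on[on] &= contig_of[gid[on]] >= 0
    read_of, offset, fwd, gid = read_of[on], offset[on], fwd[on], gid[on]
    order = np.lexsort((offset, read_of))
    first = np.flatnonzero(
        np.concatenate(([True], read_of[order][1:] != read_of[order][:-1]))
    )
    anchors = {}
    k = ctx.params.k
    for i in order[first]:
        ci = int(contig_of[gid[i]])
        cp = int(pos_of[gid[i]])
        aligned_fwd = bool(fwd[i]) == bool(strand_of[gid[i]])
        L = len(ctx.reads.seqs[int(read_of[i])])
        if aligned_fwd:
            start = cp - int(offset[i])
        else:
            start = cp - (L - k - int(offset[i]))
        anchors[int(read_of[i])] = (ci, start, aligned_fwd)
    return anchors


def scaffold(
    paths: list[ContigPath],
    ctx: AssemblyContext,
    contig_names: list[str] | None = None,
) -> list[tuple[str, str]]:
    """Order and orient contigs using read pairs.

    Two contig ends are linked when at least ``scaffold_min_links`` pairs
    agree in orientation and implied gap; the gap is filled with
    ``max(1, round(mean_insert - observed span))`` Ns.  Conflicting links on
    one contig end keep the higher-support link; singletons pass through.
    """
    p = ctx.params
    if not paths:
        return []
    anchors = _contig_read_anchors(ctx, paths)
    lens = [pt.nt for pt in paths]
    link_pairs: dict[tuple, list[float]] = {}
    for r, (ci, start, afwd) in anchors.items():
        mt = int(ctx.reads.mate[r]) if r < len(ctx.reads.mate) else -1
        if mt < 0 or mt <= r or mt not in anchors:
            continue
        cj, mstart, mfwd = anchors[mt]
        if cj == ci:
            continue
        side_i = "R" if afwd else "L"
        side_j = "R" if mfwd else "L"
        Li = len(ctx.reads.seqs[r])
        Lj = len(ctx.reads.seqs[mt])
        dist_i = lens[ci] - start if afwd else start + Li
        dist_j = lens[cj] - mstart if mfwd else mstart + Lj
        gap = ctx.insert_mean - (dist_i + dist_j)
        a, b = (ci, side_i), (cj, side_j)
        if b < a:
            a, b = b, a
        link_pairs.setdefault((a, b), []).append(gap)

    links = []
    for (a, b), gaps in link_pairs.items():
        if len(gaps) >= p.scaffold_min_links:
            links.append((len(gaps), a, b, float(np.mean(gaps))))
    links.sort(key=lambda l: (-l[0], l[1], l[2]))
    used_end: dict[tuple, tuple] = {}
    kept = []
    for support, a, b, gap in links:
        if a in used_end or b in used_end:
            log.info("dropping conflicting scaffold link %s-%s (support %d)", a, b, support)
            continue
        used_end[a] = b
        used_end[b] = a
        kept.append((a, b, gap))

    # build chains over contig ends
    adj: dict[tuple, tuple[tuple, float]] = {}
    for a, b, gap in kept:
        adj[a] = (b, gap)
        adj[b] = (a, gap)
    visited = set()
    scaffolds: list[str] = []
    order = sorted(range(len(paths)), key=lambda i: (-lens[i], paths[i].sequence))
    for ci in order:
        if ci in visited:
            continue
        # find a chain start: walk left as far as possible
        cur, enter = ci, "L"
        seen_local = {ci}
        while (cur, enter) in adj:
            nxt_end, _ = adj[(cur, enter)]
            ncontig, nside = nxt_end
            if ncontig in seen_local:
                break
            cur, enter = ncontig, "L" if nside == "R" else "R"
            seen_local.add(ncontig)
        # walk right from the start, emitting
        seq_parts = []
        cpos, centender = cur, enter
        exit_side = "R" if centender == "L" else "L"
        while True:
            visited.add(cpos)
            s = paths[cpos].sequence
            seq_parts.append(s if centender == "L" else revcomp(s))
            key = (cpos, exit_side)
            if key not in adj:
                break
            (ncontig, nside), gap = adj[key]
            if ncontig in visited:
                break
            seq_parts.append("N" * max(1, int(round(gap))))
            cpos = ncontig
            centender = nside
            exit_side = "R" if nside == "L" else "L"
        seq = "".join(seq_parts)
        if "N" not in seq:
            seq = min(seq, revcomp(seq))  # canonical orientation
        scaffolds.append(seq)
    scaffolds.sort(key=lambda s: (-len(s), s))
    return [(f"scaffold_{i + 1:05d}", s) for i, s in enumerate(scaffolds)]
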