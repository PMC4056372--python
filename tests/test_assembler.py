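"""Seeds, local coverage statistics, markers, voting and scaffolding."""

import numpy as np
import pytest

from metadbg.assembler import (
    AssemblyContext,
    AssemblyParams,
    _decide,
    _Walk,
    assemble,
    estimate_insert_size,
    find_seeds,
    seed_local_coverage,
    select_read_markers,
)
from metadbg.graph import build_graph
from metadbg.io import ReadSet
from metadbg.kmers import revcomp

K = 31


def random_dna(seed, n):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def tile(seq, length=100, step=5, copies=1):
    reads = [seq[i : i + length] for i in range(0, len(seq) - length + 1, step)]
    reads.append(seq[-length:])
    return reads * copies


# --------------------------------------------------------------------- seeds


def test_single_seed_from_linear_sequence():
    genome = random_dna(1, 300)
    g = build_graph([genome] * 2, K)  # uniform coverage 2 -> all present
    seeds = find_seeds(g)
    assert len(seeds) == 1
    s = seeds[0]
    assert s.nt == 300
    assert s.sequence in (genome, revcomp(genome))


def test_branch_splits_seeds():
    prefix = random_dna(2, 150)
    a = prefix + random_dna(3, 150)
    b = prefix + random_dna(4, 150)
    g = build_graph([a, b] * 2, K)
    seeds = find_seeds(g)
    assert 1 <= len(seeds) <= 3
    # no seed may cross the branch point
    for s in seeds:
        assert (s.sequence in a or revcomp(s.sequence) in a
                or s.sequence in b or revcomp(s.sequence) in b)


def test_empty_graph_has_no_seeds():
    assert find_seeds(build_graph([], K)) == []


def test_seeds_ignore_low_coverage_vertices():
    genome = random_dna(5, 200)
    noise = random_dna(6, 80)
    g = build_graph([genome] * 2 + [noise], K)  # noise coverage 1 < cov_present
    seeds = find_seeds(g)
    assert len(seeds) == 1 and seeds[0].nt == 200


def test_seed_stats_mode_tie_breaks_low():
    s = random_dna(7, 90)  # 60 k-mers
    g = build_graph([s] * 3 + [s[:60]] * 2, K)  # 30 k-mers at 5, 30 at 3
    seeds = find_seeds(g)
    assert len(seeds) == 1
    stats = seed_local_coverage(seeds[0], g)
    assert stats.minimum == 3
    assert stats.mode == 3  # tie between 3 and 5 breaks toward the smaller
    assert stats.mode in stats.coverages


# ------------------------------------------------------------------- markers


def test_marker_at_first_kmer_of_read():
    genome = random_dna(8, 300)
    g = build_graph([genome] * 3, K)
    seed = find_seeds(g)[0]
    stats = seed_local_coverage(seed, g)
    query = genome[40:160]
    reads = ReadSet(ids=["q"], seqs=[query])
    markers = select_read_markers(reads, seed, stats, g)
    assert len(markers) == 1
    m = markers[0]
    assert m.read_offset == 0  # first k-mer qualifies
    # the anchoring k-mer really is the read's k-mer at the recorded offset
    walk_word = seed.sequence[m.path_offset : m.path_offset + K]
    read_word = query[m.read_offset : m.read_offset + K]
    assert walk_word in (read_word, revcomp(read_word))


def test_marker_skips_repeat_coverage_kmer():
    genome = random_dna(9, 300)
    repeat = genome[50 : 50 + K]
    g = build_graph([genome] * 3 + [repeat] * 30, K)  # one k-mer at 33x
    seed = find_seeds(g)[0]
    stats = seed_local_coverage(seed, g)
    assert stats.mode == 3
    query = genome[50:170]
    markers = select_read_markers(ReadSet(ids=["q"], seqs=[query]), seed, stats, g)
    assert len(markers) == 1
    assert markers[0].read_offset == 1  # offset 0 exceeds 3x mode, skipped


def test_no_marker_without_shared_kmer():
    genome = random_dna(10, 300)
    g = build_graph([genome] * 3, K)
    seed = find_seeds(g)[0]
    stats = seed_local_coverage(seed, g)
    markers = select_read_markers(
        ReadSet(ids=["q"], seqs=[random_dna(11, 120)]), seed, stats, g
    )
    assert markers == []


# -------------------------------------------------------------- insert sizes


def make_pairs(genome, starts, insert, rl=100):
    ids1 = [f"p{i}/1" for i in range(len(starts))]
    ids2 = [f"p{i}/2" for i in range(len(starts))]
    s1 = [genome[s : s + rl] for s in starts]
    s2 = [revcomp(genome[s + insert - rl : s + insert]) for s in starts]
    return ReadSet.from_pairs(ids1, s1, ids2, s2)


def test_constant_insert_recovered_exactly():
    genome = random_dna(12, 2000)
    reads = make_pairs(genome, list(range(0, 1600, 40)), insert=300)
    g = build_graph(list(reads), K)
    params = AssemblyParams(k=K)
    ctx = AssemblyContext.prepare(g, reads, params)
    assert ctx.insert_n >= 30
    assert ctx.insert_mean == pytest.approx(300.0)
    assert ctx.insert_sd == 0.0


def test_insert_falls_back_to_prior_for_discordant_pairs():
    a = random_dna(13, 400)
    b = random_dna(14, 400)
    ids1 = [f"p{i}/1" for i in range(40)]
    ids2 = [f"p{i}/2" for i in range(40)]
    reads = ReadSet.from_pairs(
        ids1, [a[i : i + 100] for i in range(0, 200, 5)],
        ids2, [b[i : i + 100] for i in range(0, 200, 5)],
    )
    g = build_graph(list(reads), K)
    ctx = AssemblyContext.prepare(g, reads, AssemblyParams(k=K))
    assert ctx.insert_n == 0
    assert (ctx.insert_mean, ctx.insert_sd) == AssemblyParams().insert_prior


# -------------------------------------------------------------------- voting


def _toy_ctx():
    g = build_graph([random_dna(15, 100)], K)
    reads = ReadSet(ids=[], seqs=[])
    return AssemblyContext(
        graph=g, params=AssemblyParams(k=K), reads=reads, seeds=[], stats=[],
        vertex_seed=np.full(len(g), -1, dtype=np.int64),
        vertex_pos=np.zeros(len(g), dtype=np.int64),
        markers_at={}, insert_mean=400.0, insert_sd=40.0, insert_n=0,
        claimed=np.zeros(len(g), dtype=bool), read_bytes=[], max_read_len=100,
    )


def _voting_walk(votes_by_base):
    w = _Walk()
    w.seq = bytearray(b"A" * 50)
    for base, n in votes_by_base.items():
        for i in range(n):
            seq = (b"A" * 49) + base.encode()  # base read at position 50
            w.active.append((seq, 1, 1000 + len(w.active), True))
    return w


def test_vote_majority_wins_two_to_one():
    ctx = _toy_ctx()
    w = _voting_walk({"A": 5, "C": 1})
    cands = [(0, 0, 0, True, 0, 5), (1, 0, 0, True, 0, 5)]  # A and C, both present
    choice, reason = _decide(ctx, w, cands)
    assert reason is None and choice[0] == 0  # A chosen: 5 >= 2 and 5 >= 2*1


def test_vote_tie_stops_ambiguous():
    ctx = _toy_ctx()
    w = _voting_walk({"A": 1, "C": 1})
    cands = [(0, 0, 0, True, 0, 5), (1, 0, 0, True, 0, 5)]
    choice, reason = _decide(ctx, w, cands)
    assert choice is None and reason == "ambiguous"


def test_single_subfloor_candidate_needs_votes():
    ctx = _toy_ctx()
    cands = [(0, 0, 0, True, 0, 1)]  # coverage 1 < cov_present
    choice, reason = _decide(ctx, _voting_walk({"A": 1}), cands)
    assert choice is None and reason == "ambiguous"
    choice, reason = _decide(ctx, _voting_walk({"A": 3}), cands)
    assert reason is None and choice[0] == 0


def test_no_candidates_stops():
    ctx = _toy_ctx()
    choice, reason = _decide(ctx, _voting_walk({}), [])
    assert choice is None and reason == "no-successor"


# ------------------------------------------------------------------ assembly


def test_error_free_genome_reconstructed_exactly():
    genome = random_dna(16, 1000)
    res = assemble(tile(genome, copies=2), K)
    assert len(res.contigs) == 1
    seq = res.contigs[0][1]
    assert seq in (genome, revcomp(genome))
    p = res.paths[0]
    assert p.left_stop == "no-successor" and p.right_stop == "no-successor"


def test_contig_walk_revalidates_against_graph():
    genome = random_dna(17, 800)
    reads = tile(genome)
    res = assemble(reads, K)
    g = build_graph(reads, K)
    for p in res.paths:
        assert len(p.sequence) == len(p) + K - 1
        # consecutive canonical k-mers overlap by k-1 along the sequence
        for i in range(len(p)):
            w = p.sequence[i : i + K]
            assert g.gid_of(w) == p.gids[i]


def test_strand_invariance():
    genome = random_dna(18, 900)
    reads = tile(genome)
    a = sorted(s for _, s in assemble(reads, K).contigs)
    b = sorted(s for _, s in assemble([revcomp(r) for r in reads], K).contigs)
    assert a == b


def test_read_order_and_shard_invariance():
    genome = random_dna(19, 900)
    reads = tile(genome, copies=2)
    ref = assemble(reads, K).contigs
    rng = np.random.default_rng(0)
    shuffled = list(reads)
    rng.shuffle(shuffled)
    assert assemble(shuffled, K).contigs == ref
    assert assemble(reads, K, AssemblyParams(k=K, n_shards=1)).contigs == ref
    assert assemble(reads, K, AssemblyParams(k=K, n_shards=8)).contigs == ref


def test_determinism_byte_identical():
    genome = random_dna(20, 700)
    reads = tile(genome)
    assert assemble(reads, K).contigs == assemble(reads, K).contigs


def test_circular_sequence_stops_with_cycle():
    genome = random_dna(21, 400)
    wrap = genome + genome[:120]
    reads = tile(wrap, length=100, step=4, copies=2)
    res = assemble(reads, K)
    stops = {p.left_stop for p in res.paths} | {p.right_stop for p in res.paths}
    assert "cycle" in stops


def test_short_reads_only_yield_empty_assembly():
    res = assemble(["ACGT", "TTTT"], K)
    assert res.contigs == [] and res.scaffolds == []


def test_too_small_contigs_suppressed():
    genome = random_dna(22, 120)  # below the 2k-1=61? no: seed ok, contig 120 >= 100
    tiny = random_dna(23, 80)  # contig of 80 nt < 100 floor
    res = assemble([genome] * 2 + [tiny] * 2, K)
    lengths = sorted(len(s) for _, s in res.contigs)
    assert lengths == [120]
    assert res.report["n_contigs_all"] == 2


# ----------------------------------------------------------------- scaffolds


def test_scaffold_links_contigs_across_gap():
    genome = random_dna(24, 3000)
    left = tile(genome[:1400], length=100, step=5)
    right = tile(genome[1600:], length=100, step=5)
    spanning = []
    ids1, s1, ids2, s2 = [], [], [], []
    for i, s in enumerate(range(1250, 1330, 16)):
        ids1.append(f"sp{i}/1")
        s1.append(genome[s : s + 100])
        ids2.append(f"sp{i}/2")
        s2.append(revcomp(genome[s + 320 : s + 420]))
    pairs = ReadSet.from_pairs(ids1, s1, ids2, s2)
    all_reads = ReadSet(
        ids=[f"u{i}" for i in range(len(left + right))] + pairs.ids,
        seqs=left + right + pairs.seqs,
    )
    all_reads.mate[len(left + right) :] = np.where(
        pairs.mate >= 0, pairs.mate + len(left + right), -1
    )
    res = assemble(all_reads, K)
    assert len(res.contigs) == 2
    assert len(res.scaffolds) == 1
    sc = res.scaffolds[0][1]
    assert "N" in sc
    assert len(sc) > max(len(s) for _, s in res.contigs)


def test_two_supporting_pairs_do_not_link():
    genome = random_dna(25, 3000)
    left = tile(genome[:1400], length=100, step=5)
    right = tile(genome[1600:], length=100, step=5)
    ids1, s1, ids2, s2 = [], [], [], []
    for i, s in enumerate((1250, 1290)):  # only 2 pairs < 3 required
        ids1.append(f"sp{i}/1")
        s1.append(genome[s : s + 100])
        ids2.append(f"sp{i}/2")
        s2.append(revcomp(genome[s + 320 : s + 420]))
    pairs = ReadSet.from_pairs(ids1, s1, ids2, s2)
    all_reads = ReadSet(
        ids=[f"u{i}" for i in range(len(left + right))] + pairs.ids,
        seqs=left + right + pairs.seqs,
    )
    all_reads.mate[len(left + right) :] = np.where(
        pairs.mate >= 0, pairs.mate + len(left + right), -1
    )
    res = assemble(all_reads, K)
    assert len(res.scaffolds) == len(res.contigs)  # singletons pass through
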