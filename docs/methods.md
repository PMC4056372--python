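# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.  Everything stated here is computed by the
package's own tests or scripts; nothing is quoted from external runs.

## Graph construction

Reads are concatenated with separator symbols and every clean length-k
window (k odd, ≤ 31; default 31) is packed 2 bits per base (A=0, C=1, G=2,
T=3), so packed order equals lexicographic order and the canonical form is
simply `min(word, revcomp(word))`.  Odd k guarantees no word is its own
reverse complement, so the strand flag is always defined.  Vertices are the
distinct canonical codes (found with one `np.unique` pass, which also makes
construction independent of read order); coverage is the occurrence count
over both strands, stored as uint16 and saturating at 65,535 (saturation is
counted and logged).  Edge marks are derived only from window pairs adjacent
within a read: for an observed (k+1)-mer the prefix vertex gets an out-mark
and the suffix vertex an in-mark, each translated through the canonical
orientation.  No coverage floor is applied at build time; erroneous k-mers
(almost all coverage 1) are filtered by traversal, not storage.

Sharding is a logical contract standing in for a distributed hash table: the
store keeps global sorted arrays, and shard s owns the vertices with
`splitmix64(code) mod S == s`.  A full-scan check (`check_shards`) verifies
membership; tests assert that serialisations for S ∈ {1, 4, 8} are
byte-identical.

## Assembly

*Seeds.*  A vertex is **present** when its coverage is at least
`cov_present` (default 2).  Seeds are maximal chains in which every internal
vertex has exactly one present neighbour on each side, discovered by a
vectorised degree table plus a linear chain walk; isolated cycles are broken
deterministically at their smallest-code vertex.  Seeds shorter than
`min_seed_nt` (default 2k−1 = 61 nt) are discarded; survivors are oriented
canonically and sorted by sequence, which makes seed identity independent of
read order and strand.

*Local statistics.*  Each seed's modal and minimum coverage are computed
from the seed's own vertices only (ties in the mode break toward the smaller
value).  The assembler has no access to a whole-graph coverage histogram:
`coverage_histogram` exists as a diagnostic, and a test asserts assembly
output is identical whether or not coloring (or any other read-only
consumer) has touched the graph.

*Markers and insert size.*  A read yields at most one marker per seed: its
first k-mer that lies on the seed with coverage within
[seed minimum, `repeat_mult`·mode] (`repeat_mult` = 3; the upper cut avoids
anchoring in repeats).  Pairs whose two mates are markered on one seed give
outer fragment lengths; after discarding the top and bottom 5%, their mean
and sd estimate the insert distribution, falling back to the configured
prior (400 ± 40 nt) below 30 usable pairs.

*Extension.*  Extension proceeds one vertex at a time from both seed ends
(the left side is handled by reverse-complementing the walk state and
re-running the right-extension code).  Candidate successors are the
marked-edge neighbours; when any candidate is present, the candidate pool is
restricted to the present ones.  A single present candidate is taken
outright.  Every other situation is put to a vote: each read anchored on the
walk and overlapping the decision position votes for the base it reads
there; if the read votes are inconclusive, mates of on-path reads projected
at the estimated insert (window mean ± 3 sd) add their votes.  The top base
wins only with ≥ `vote_min` (2) votes and ≥ `vote_ratio` (2×) the runner-up;
otherwise the walk stops with reason `ambiguous`.  Re-entering the current
walk stops with `cycle`; stepping onto a vertex claimed by a previously
emitted contig stops with `conflict`.

Two design points here were genuinely open and are this package's choices:

1. The defining rule ("vote at a branch of present successors") says nothing
   about a step whose *sole* successor is below the presence floor.  We
   follow it, but demand the vote rule be satisfied.  Poisson coverage
   arithmetic shows why: at k-mer depth λ ≈ 6–7 (the tail of a power-law
   community), about 1% of k-mer positions have coverage ≤ 1, and stopping
   at each would shred low-abundance genomes; conversely, crossing without a
   vote would append single-read error chains (~30 wrong bases) to contig
   ends.  Requiring ≥ 2 concordant read votes crosses genuine coverage dips
   (several reads overlap the position even when only one spans the whole
   window) while single-read error chains fail the vote.
2. `conflict` claiming: seeds are processed longest-first, each extension
   claims its vertices, and later seeds whose vertices are all claimed are
   skipped.  This both bounds total traversal work by the genome size and
   implements the containment rule (a contig fully inside another's walk is
   never emitted).  Its cost: a genuinely branching locus reachable from two
   seeds is assembled once, from whichever seed is processed first.

Contigs are emitted as `min(seq, revcomp(seq))`, deduplicated by sequence,
and filtered at `min_contig_nt` (100 nt) for default output; the run report
keeps the unfiltered count and the stop-reason tally.  All constants above
are exposed in `AssemblyParams` and on the command line; the defaults favour
correctness over contiguity.

*Scaffolding.*  A read anchored on a contig implies its mate's position and
orientation; two contig ends are linked when ≥ `scaffold_min_links` (3)
pairs agree, the per-pair implied gap being `insert − span`.  Conflicting
links on one end keep the higher support (dropped links are logged).  Chains
are walked from free ends; gaps are filled with `max(1, round(mean gap))`
Ns.  Singleton contigs pass through as scaffolds.

## Coloring and profiles

Colors are global integers; each belongs to one namespace, and registration
is idempotent per (namespace, reference name).  Coloring looks up each
reference's distinct canonical k-mers and adds the color to vertices already
present — never creating vertices or touching coverage, so assembly is
provably independent of it.  Color sets are interned: vertices store a set
id, and the number of set objects is bounded by the distinct combinations
seen.

Proportions follow the uniquely-colored k-mer demultiplexing rule
(`observations = matched × mode_unique`, total = summed coverage of all
colored k-mers).  Two properties matter in practice:

- **Duplicate references.**  Registering the same sequence twice leaves both
  copies without uniquely-colored k-mers; both are reported with proportion
  0 and a `no-unique-kmers` flag, while LCA profiling still credits their
  shared coverage to the common parent taxon.
- **Discretisation bias.**  `mode_unique` is an integer ≈ ⌊λ⌋ for Poisson
  coverage at rate λ, so each proportion is biased low by roughly 0.5/λ
  relative.  At the test conditions (top k-mer depth 30, α = −0.5, ten
  genomes) the worst absolute error is ~0.006; at half that depth it reaches
  the 0.01 level.  This is a property of the estimator, not of the
  implementation.

Taxonomic profiling maps each color to a taxonomy node and assigns each
colored vertex's full coverage to the LCA of its color set (computed by
depth-aligned ancestor walks; an oracle test checks 1,000 random color sets
against brute-force root-path intersection).  Per-rank tables use subtree
sums plus an "unclassified at this rank" bucket so every rank conserves the
exact integer observation total.  The alternative — splitting a shared
k-mer's coverage among leaves — would change printed semantics and is not
implemented.  GO profiling counts flat terms (each vertex's coverage once
per distinct term among its colors' annotations; no DAG up-propagation);
vertices whose colors carry no annotation land in an `unannotated` bucket.

## Simulator

The simulator draws i.i.d. uniform ACGT genomes, a host genome for
contamination, and optional near-duplicates (per-base substitutions at a
divergence rate).  Community structure is the rank/abundance power law
p_i ∝ i^α; p_i is interpreted as the *pair-sampling* probability, which for
constant read length equals the nucleotide proportion.  Each pair draws a
genome (host with probability = contamination), an insert from
Normal(μ, σ) rounded and truncated to ≥ read length (resampled up to 20
times if longer than the genome, then clipped), a uniform fragment start,
and a strand; R2 is the reverse-complement end of the fragment.
Substitutions are i.i.d. per base, uniform over the three other bases.
Defaults mirror a published 100-genome design scaled down: read length 101,
error rate 0.25%, insert mean 400 (sd defaulting to 10% of the mean — only
the mean is published, and a spread is needed for realism and scaffold
testing), contamination 1%, α = −0.5.  Everything is generated from
`default_rng([seed, stream])`, so outputs are byte-identical per seed.

The helper `pairs_for_kmer_depth` sizes an experiment by expected k-mer
coverage depth of the most abundant genome — coverage depth in the graph's
sense (windows per k-mer), the package's coverage currency; the test suite's
community experiment uses a top depth of 30 in these units.

What the simulator does **not** model: indels, quality-score error profiles,
GC or positional bias, real genome repeat structure, strain-level shared
k-mer content (except through explicit near-duplicates), and uneven genome
sizes within a community unless configured.  Consequently the green test
suite shows that the algorithms are implemented correctly and behave as
designed on data matching their assumptions; it does not certify assembly
quality on real libraries, where repeats and indel errors dominate the
failure modes.

## Evaluation

Contigs are aligned with maximal exact matches ≥ `anchor_min` (default k)
found by canonical k-mer seeding and same-diagonal run merging, then chained
colinearly per reference and strand (quadratic DP over a handful of anchors;
up to four chains are extracted per reference/strand so a contig wrapping a
circular origin yields both parts).  A contig passes the misassembly test
iff its best single chain spans ≥ 98% of its length, or exactly two chains
abut the start and end of one reference (tolerance k) with combined span
≥ 98%.  Breadth of coverage is the union of placed reference intervals over
the reference length.  Mismatch counts are approximated by inter-anchor gap
bases within a chain and labelled approximate; exact anchors are adequate
for the simulator's substitution-only, known-truth data and were chosen over
a full aligner for that reason.  N50 is the largest L with
Σ(lengths ≥ L) ≥ total/2, over sequences ≥ a 100 nt floor (500 nt for the
misassembly test, matching the reporting convention mirrored here).

## Problem sizes and determinism

The test suite's largest experiment is ten 100 kb genomes at top k-mer depth
30 with 1% contamination (~107k pairs, ~21.6 Mb of read bases); it runs in a
few minutes on one core and is the scale at which all end-to-end claims
(breadth ≥ 95% at depth ≥ 10×, ≤ 2% misassembled contigs ≥ 500 nt,
proportion error ≤ 0.01 with r ≥ 0.99 against the realized composition) are
asserted.  Calibration measurements use ≥ 10⁷ read bases (error rate) and
10⁶ pairs (insert mean).  Every stochastic step takes an explicit seed; two
runs with the same inputs and seed produce byte-identical FASTA/TSV/JSON, and
the suite additionally asserts invariance of assembly output to read order,
strand flips of the input, and shard count.

## Known limitations

- k ≤ 31 (one 64-bit word); no spaced seeds or minimizers.
- Graph topology is never simplified (no tip clipping or bubble popping by
  design — traversal rules do the filtering), so very high error rates
  inflate memory.
- The voting heuristic is a faithful-in-spirit stand-in for the original
  distributed assembler's marker machinery, whose exact formulas are not
  restated in the source we mirror; constants are conservative and surfaced
  in config.
- Scaffolding uses single-link chains with majority conflict resolution; no
  global ordering optimisation.
- The exact-anchor evaluator under-counts breadth near substitutions
  (window-length shadows) and does not model indels.
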