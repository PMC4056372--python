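"""Synthetic metagenome generator with full truth tracking.

Emulates the statistical structure of desk-scale shotgun metagenome
experiments: community composition following a rank/abundance power law
(proportion of the i-th most abundant genome proportional to ``i**alpha``),
paired-end reads with a Normal insert-length distribution, uniform i.i.d.
substitution errors, optional host contamination and optional near-duplicate
genomes (to reproduce the failure mode in which two nearly identical
references share almost all their k-mers).  Matching taxonomy and
gene-ontology fixtures are generated alongside, so the whole profiling stack
can run on simulated data with known truth.

Defaults mirror a published 100-genome simulation design scaled down: read
length 101 nt, substitution error rate 0.25%, mean insert 400 nt, 1% host
contamination and power-law exponent -0.5.  The insert-length standard
deviation defaults to 10% of the mean.  Abundances are interpreted as
pair-sampling probabilities, which for constant read length equal nucleotide
proportions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ReadSet, write_fasta, write_fastq, write_table
from .profiling import RANKS

__all__ = [
    "SimulationConfig",
    "power_law_proportions",
    "simulate_genomes",
    "simulate_reads",
    "simulate_references",
    "pairs_for_depth",
    "GenomeSet",
    "ReadSim",
    "RefPack",
]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated experiment; ``seed`` is mandatory."""

    seed: int
    n_genomes: int = 10
    genome_length: int | Sequence[int] = 100_000
    alpha: float = -0.5
    n_read_pairs: int = 10_000
    read_length: int = 101
    error_rate: float = 0.0025
    insert_mean: float = 400.0
    insert_sd: float | None = None  # None -> 10% of the mean
    contamination: float = 0.01
    host_length: int = 100_000
    duplicates: tuple[tuple[int, float], ...] = ()  # (source index, divergence)

    def __post_init__(self):
        for rate in (self.error_rate, self.contamination, *(d for _, d in self.duplicates)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must lie in [0,1], got {rate}")
        if min(self.lengths()) < self.read_length:
            raise ValueError("genome length must be >= read length")
        if self.n_genomes < 1:
            raise ValueError("need at least one genome")

    def lengths(self) -> list[int]:
        if isinstance(self.genome_length, int):
            return [self.genome_length] * self.n_genomes
        if len(self.genome_length) != self.n_genomes:
            raise ValueError("genome_length list must have n_genomes entries")
        return list(self.genome_length)

    @property
    def sd(self) -> float:
        return 0.1 * self.insert_mean if self.insert_sd is None else self.insert_sd

    def echo_json(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class GenomeSet:
    names: list[str]
    seqs: list[str]
    host_name: str | None = None
    host_seq: str | None = None
    dup_names: list[str] = field(default_factory=list)
    dup_seqs: list[str] = field(default_factory=list)
    dup_sources: list[str] = field(default_factory=list)

    def references(self) -> list[tuple[str, str]]:
        """Bacterial genomes plus near-duplicates, as coloring references."""
        return list(zip(self.names, self.seqs)) + list(zip(self.dup_names, self.dup_seqs))

    def encoded(self) -> list[np.ndarray]:
        from .kmers import encode_sequence

        return [encode_sequence(s) for s in self.seqs]


@dataclass
class ReadSim:
    """Simulated paired reads with per-read truth."""

    config: SimulationConfig
    r1: np.ndarray  # (n_pairs, read_length) uint8 base codes, as sequenced
    r2: np.ndarray
    pair_genome: np.ndarray  # genome index, -1 for host
    pair_start: np.ndarray  # fragment start on the forward strand
    pair_insert: np.ndarray
    pair_strand: np.ndarray  # True: R1 is the forward-strand read
    genome_names: list[str]

    @property
    def n_pairs(self) -> int:
        return int(self.r1.shape[0])

    def read_ids(self) -> tuple[list[str], list[str]]:
        return (
            [f"p{i:07d}/1" for i in range(self.n_pairs)],
            [f"p{i:07d}/2" for i in range(self.n_pairs)],
        )

    def sequences(self) -> tuple[list[str], list[str]]:
        s1 = [bytes(_ACGT[row]).decode() for row in self.r1]
        s2 = [bytes(_ACGT[row]).decode() for row in self.r2]
        return s1, s2

    def reads(self) -> ReadSet:
        ids1, ids2 = self.read_ids()
        s1, s2 = self.sequences()
        return ReadSet.from_pairs(ids1, s1, ids2, s2)

    def truth(self) -> pd.DataFrame:
        """Per-read truth table: read_id, genome, 0-based start, strand."""
        rl = self.config.read_length
        ids1, ids2 = self.read_ids()
        names = np.array(self.genome_names + ["host"], dtype=object)
        gname = names[self.pair_genome]  # -1 indexes the appended host name
        s_fwd = self.pair_start
        s_rev = self.pair_start + self.pair_insert - rl
        r1_start = np.where(self.pair_strand, s_fwd, s_rev)
        r2_start = np.where(self.pair_strand, s_rev, s_fwd)
        r1_strand = np.where(self.pair_strand, "+", "-")
        r2_strand = np.where(self.pair_strand, "-", "+")
        df = pd.DataFrame(
            {
                "read_id": ids1 + ids2,
                "genome": np.concatenate([gname, gname]),
                "start": np.concatenate([r1_start, r2_start]),
                "strand": np.concatenate([r1_strand, r2_strand]),
            }
        )
        return df


def power_law_proportions(n: int, alpha: float) -> np.ndarray:
    """Rank/abundance proportions p_i = i**alpha / sum_j j**alpha, i = 1..n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    w = np.arange(1, n + 1, dtype=float) ** alpha
    return w / w.sum()


def pairs_for_depth(top_depth: float, config: SimulationConfig) -> int:
    """Pair count so the most abundant genome reaches the given base depth."""
    p = power_law_proportions(config.n_genomes, config.alpha)
    len1 = config.lengths()[0]
    n_bact = top_depth * len1 / (2 * config.read_length * p[0])
    return int(round(n_bact / (1.0 - config.contamination)))


def pairs_for_kmer_depth(top_depth: float, config: SimulationConfig, k: int = 31) -> int:
    """Pair count so the most abundant genome's expected k-mer coverage is
    ``top_depth`` (coverage depth in the graph's sense: windows per k-mer)."""
    rl = config.read_length
    base_depth = top_depth * rl / (rl - k + 1)
    return pairs_for_depth(base_depth, config)


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return bytes(_ACGT[rng.integers(0, 4, size=length)]).decode()


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    enc = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.zeros(enc.size, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[enc == b] = i
    hit = rng.random(enc.size) < rate
    shift = rng.integers(1, 4, size=enc.size).astype(np.uint8)
    code = np.where(hit, (code + shift) % 4, code)
    return bytes(_ACGT[code]).decode()


def simulate_genomes(config: SimulationConfig) -> GenomeSet:
    """Draw i.i.d. uniform-ACGT genomes (plus host and near-duplicates)."""
    rng = np.random.default_rng([config.seed, 0])
    names = [f"g{i + 1:02d}" for i in range(config.n_genomes)]
    seqs = [_random_genome(rng, L) for L in config.lengths()]
    gs = GenomeSet(names=names, seqs=seqs)
    if config.contamination > 0:
        gs.host_name = "host"
        gs.host_seq = _random_genome(rng, config.host_length)
    for src, div in config.duplicates:
        gs.dup_names.append(f"{names[src]}_dup")
        gs.dup_seqs.append(_diverge(rng, seqs[src], div))
        gs.dup_sources.append(names[src])
    return gs


def simulate_reads(config: SimulationConfig, genomes: GenomeSet) -> ReadSim:
    """Draw paired reads: genome by abundance, fragment uniform, errors i.i.d.

    Each pair comes from bacterial genome i with probability
    ``(1 - contamination) * p_i`` and from the host otherwise.  The insert is
    Normal(mean, sd) truncated to at least the read length (resampled, with a
    retry cap, when it exceeds the genome).  R2 is the reverse-complement end
    of the fragment; with probability 1/2 the fragment is sequenced from the
    opposite strand, swapping the roles of the two mates.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_read_pairs
    rl = config.read_length
    p = power_law_proportions(config.n_genomes, config.alpha)
    lengths = np.array(config.lengths() + [config.host_length], dtype=np.int64)

    gidx = rng.choice(config.n_genomes, size=n, p=p).astype(np.int64)
    if config.contamination > 0:
        host = rng.random(n) < config.contamination
        gidx[host] = -1
        if genomes.host_seq is None:
            raise ValueError("contamination requested but GenomeSet has no host")
    glen = lengths[gidx]

    insert = np.rint(rng.normal(config.insert_mean, config.sd, size=n)).astype(np.int64)
    for _ in range(20):  # resample out-of-range inserts, then clip
        bad = (insert < rl) | (insert > glen)
        if not bad.any():
            break
        insert[bad] = np.rint(
            rng.normal(config.insert_mean, config.sd, size=int(bad.sum()))
        ).astype(np.int64)
    np.clip(insert, rl, glen, out=insert)

    start = rng.integers(0, glen - insert + 1)
    strand = rng.random(n) < 0.5  # True: R1 is the forward-strand read

    enc = {i: g for i, g in enumerate(genomes.encoded())}
    if genomes.host_seq is not None:
        from .kmers import encode_sequence

        enc[-1] = encode_sequence(genomes.host_seq)

    fwd = np.empty((n, rl), dtype=np.uint8)  # forward-strand read of each pair
    rev = np.empty((n, rl), dtype=np.uint8)  # reverse-strand read (as sequenced)
    offs = np.arange(rl, dtype=np.int64)
    for g in np.unique(gidx):
        sel = np.flatnonzero(gidx == g)
        gseq = enc[int(g)]
        fwd[sel] = gseq[start[sel, None] + offs]
        tail = gseq[(start[sel] + insert[sel] - rl)[:, None] + offs]
        rev[sel] = (3 - tail)[:, ::-1]  # reverse complement in code space

    r1 = np.where(strand[:, None], fwd, rev)
    r2 = np.where(strand[:, None], rev, fwd)

    if config.error_rate > 0:
        for mat in (r1, r2):
            hit = rng.random(mat.shape) < config.error_rate
            shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
            mat[hit] = (mat[hit] + shift[hit]) % 4

    return ReadSim(
        config=config,
        r1=r1,
        r2=r2,
        pair_genome=gidx,
        pair_start=start,
        pair_insert=insert,
        pair_strand=strand,
        genome_names=list(genomes.names),
    )


def empirical_error_rate(sim: ReadSim, genomes: GenomeSet) -> tuple[float, int]:
    """Observed per-base mismatch fraction of reads against their truth placement.

    Returns ``(rate, n_bases)``.
    """
    rl = sim.config.read_length
    enc = {i: g for i, g in enumerate(genomes.encoded())}
    if genomes.host_seq is not None:
        from .kmers import encode_sequence

        enc[-1] = encode_sequence(genomes.host_seq)
    offs = np.arange(rl, dtype=np.int64)
    mism = 0
    for g in np.unique(sim.pair_genome):
        sel = np.flatnonzero(sim.pair_genome == g)
        gseq = enc[int(g)]
        fwd_true = gseq[sim.pair_start[sel, None] + offs]
        tail = gseq[(sim.pair_start[sel] + sim.pair_insert[sel] - rl)[:, None] + offs]
        rev_true = (3 - tail)[:, ::-1]
        s = sim.pair_strand[sel, None]
        mism += int(np.sum(np.where(s, fwd_true, rev_true) != sim.r1[sel]))
        mism += int(np.sum(np.where(s, rev_true, fwd_true) != sim.r2[sel]))
    n_bases = 2 * sim.n_pairs * rl
    return mism / n_bases, n_bases


def empirical_insert_mean(truth: pd.DataFrame, read_length: int) -> tuple[float, int]:
    """Mean outer fragment length recovered from a truth table."""
    base = truth["read_id"].str.slice(0, -2)
    g = truth.groupby(base, sort=False)["start"]
    outer = g.max() + read_length - g.min()
    return float(outer.mean()), int(outer.size)


# ---------------------------------------------------------------- references


@dataclass
class RefPack:
    taxonomy: pd.DataFrame  # node_id, parent_id, rank, name
    ref_taxon: pd.DataFrame  # reference, taxon_id
    cds: list[tuple[str, str]]  # (cds id, sequence)
    cds_meta: pd.DataFrame  # cds_id, genome, start, end
    cds_go: pd.DataFrame  # cds_id, go_id, domain

    def species_of(self, reference: str) -> int:
        row = self.ref_taxon[self.ref_taxon["reference"] == reference]
        return int(row["taxon_id"].iloc[0])


GO_DOMAINS = ["biological_process", "cellular_component", "molecular_function"]


def simulate_references(
    config: SimulationConfig,
    genomes: GenomeSet,
    cds_length: int = 900,
    cds_spacing: int = 3000,
    n_go_terms: int = 30,
    unannotated_every: int = 7,
) -> RefPack:
    """Random taxonomy, CDS slices and a synthetic GO annotation.

    The taxonomy is a rooted tree over the seven standard ranks with every
    genome attached as a species leaf; a near-duplicate becomes a sibling
    species under its source's genus.  The host, when present, hangs from its
    own kingdom.  CDS records are non-overlapping genome slices; each gets
    1-3 GO ids from a small synthetic ontology spanning the three domains,
    except every ``unannotated_every``-th CDS, which is left unannotated.
    """
    rng = np.random.default_rng([config.seed, 2])
    rows = [(1, 0, "root", "root")]
    next_id = 2
    # children bookkeeping per internal rank
    children: dict[tuple[int, str], list[int]] = {}

    def new_node(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        rows.append((nid, parent, rank, name))
        children.setdefault((parent, rank), []).append(nid)
        return nid

    genus_of: dict[str, int] = {}
    ref_rows: list[tuple[str, int]] = []
    for name in genomes.names:
        parent = 1
        for rank in RANKS[1:-1]:  # kingdom .. genus
            sibs = children.get((parent, rank), [])
            if sibs and rng.random() < 0.5:
                parent = int(sibs[rng.integers(0, len(sibs))])
            else:
                parent = new_node(parent, rank, f"{rank[0]}_{name}")
        genus_of[name] = parent
        species = new_node(parent, "species", name)
        ref_rows.append((name, species))
    for dname, src in zip(genomes.dup_names, genomes.dup_sources):
        species = new_node(genus_of[src], "species", dname)
        ref_rows.append((dname, species))
    if genomes.host_name is not None:
        parent = 1
        for rank in RANKS[1:-1]:
            parent = new_node(parent, rank, f"{rank[0]}_host")
        species = new_node(parent, "species", genomes.host_name)
        ref_rows.append((genomes.host_name, species))

    taxonomy = pd.DataFrame(rows, columns=["node_id", "parent_id", "rank", "name"])
    ref_taxon = pd.DataFrame(ref_rows, columns=["reference", "taxon_id"])

    go_ids = [f"GO:{i + 1:07d}" for i in range(n_go_terms)]
    go_domain = {g: GO_DOMAINS[i % 3] for i, g in enumerate(go_ids)}
    cds: list[tuple[str, str]] = []
    meta_rows = []
    go_rows = []
    cds_counter = 0
    for name, seq in zip(genomes.names, genomes.seqs):
        for j, startpos in enumerate(range(0, len(seq) - cds_length + 1, cds_spacing)):
            cid = f"{name}_cds{j:03d}"
            cds.append((cid, seq[startpos : startpos + cds_length]))
            meta_rows.append((cid, name, startpos, startpos + cds_length))
            cds_counter += 1
            if unannotated_every and cds_counter % unannotated_every == 0:
                continue
            nterms = int(rng.integers(1, 4))
            for gid in rng.choice(n_go_terms, size=nterms, replace=False):
                go = go_ids[int(gid)]
                go_rows.append((cid, go, go_domain[go]))
    cds_meta = pd.DataFrame(meta_rows, columns=["cds_id", "genome", "start", "end"])
    cds_go = pd.DataFrame(go_rows, columns=["cds_id", "go_id", "domain"])
    return RefPack(
        taxonomy=taxonomy, ref_taxon=ref_taxon, cds=cds, cds_meta=cds_meta, cds_go=cds_go
    )


def write_simulation(outdir: str | Path, config: SimulationConfig, genomes: GenomeSet, sim: ReadSim, refs: RefPack | None = None) -> list[Path]:
    """Write FASTQ pairs, genome FASTA, truth TSV and fixture tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def note(p: Path) -> Path:
        written.append(p)
        return p

    ids1, ids2 = sim.read_ids()
    s1, s2 = sim.sequences()
    write_fastq(note(outdir / "reads_R1.fastq"), ids1, s1)
    write_fastq(note(outdir / "reads_R2.fastq"), ids2, s2)
    records = list(zip(genomes.names, genomes.seqs)) + list(zip(genomes.dup_names, genomes.dup_seqs))
    if genomes.host_seq is not None:
        records.append((genomes.host_name, genomes.host_seq))
    write_fasta(note(outdir / "genomes.fasta"), records)
    write_table(note(outdir / "truth.tsv"), sim.truth())
    (outdir / "config.json").write_text(config.echo_json() + "\n")
    note(outdir / "config.json")
    if refs is not None:
        write_table(note(outdir / "taxonomy.tsv"), refs.taxonomy)
        write_table(note(outdir / "ref_taxon.tsv"), refs.ref_taxon)
        write_fasta(note(outdir / "cds.fasta"), refs.cds)
        write_table(note(outdir / "cds_go.tsv"), refs.cds_go)
    return written
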