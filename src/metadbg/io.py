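"""Sequence and table IO shared by all modules.

Conventions: FASTA wrapped at 80 columns; FASTQ is Phred+33; TSV files are
tab-separated without quoting and carry a single header line prefixed with
``#``; all coordinates in outputs are 0-based half-open; strands are "+"/"-".
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = [
    "ReadSet",
    "read_sequences",
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_table",
    "write_table",
    "write_manifest",
]


@dataclass
class ReadSet:
    """An in-memory read collection with optional mate pairing.

    ``mate[i]`` is the index of read i's mate, or -1 for unpaired reads.
    """

    ids: list[str]
    seqs: list[str]
    quals: list[str] | None = None
    mate: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self):
        if self.mate.size == 0 and self.ids:
            self.mate = np.full(len(self.ids), -1, dtype=np.int64)
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.seqs))

    @classmethod
    def from_pairs(cls, ids1, seqs1, ids2, seqs2) -> "ReadSet":
        """Interleave two mate lists into one set with mate links."""
        if len(ids1) != len(ids2):
            raise ValueError(
                f"pair-count mismatch: {len(ids1)} R1 reads vs {len(ids2)} R2 reads"
            )
        for i, (a, b) in enumerate(zip(ids1, ids2)):
            if _strip_mate_suffix(a) != _strip_mate_suffix(b):
                raise ValueError(f"read ids do not pair at record {i}: {a!r} vs {b!r}")
        ids: list[str] = []
        seqs: list[str] = []
        mate = np.empty(2 * len(ids1), dtype=np.int64)
        for i in range(len(ids1)):
            ids.extend((ids1[i], ids2[i]))
            seqs.extend((seqs1[i], seqs2[i]))
            mate[2 * i] = 2 * i + 1
            mate[2 * i + 1] = 2 * i
        return cls(ids=ids, seqs=seqs, mate=mate)


def _strip_mate_suffix(rid: str) -> str:
    return rid[:-2] if rid.endswith(("/1", "/2")) else rid


def _sniff_format(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"cannot detect sequence format of {path}")


def _parse_file(path: str | Path, fmt: str | None) -> tuple[list[str], list[str], list[str] | None]:
    fmt = fmt or _sniff_format(path)
    ids: list[str] = []
    seqs: list[str] = []
    quals: list[str] | None = [] if fmt == "fastq" else None
    try:
        for rec in SeqIO.parse(str(path), fmt):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
            if quals is not None:
                q = rec.letter_annotations.get("phred_quality", [])
                quals.append("".join(chr(33 + v) for v in q))
    except ValueError as exc:
        lines_per_rec = 4 if fmt == "fastq" else 2
        raise ValueError(
            f"truncated or malformed {fmt} record near line "
            f"{len(ids) * lines_per_rec + 1} of {path}: {exc}"
        ) from exc
    return ids, seqs, quals


def read_sequences(
    path: str | Path,
    fmt: str | None = None,
    pairing: str = "single",
    mate_path: str | Path | None = None,
) -> ReadSet:
    """Read FASTA/FASTQ into a :class:`ReadSet`.

    ``pairing`` is one of ``single``, ``separate`` (R1 file plus ``mate_path``)
    or ``interleaved``.  Pairing is validated: equal counts, and ids matching
    up to a ``/1``/``/2`` suffix.
    """
    ids, seqs, quals = _parse_file(path, fmt)
    if pairing == "single":
        return ReadSet(ids=ids, seqs=seqs, quals=quals)
    if pairing == "separate":
        if mate_path is None:
            raise ValueError("pairing='separate' requires mate_path")
        ids2, seqs2, _ = _parse_file(mate_path, fmt)
        return ReadSet.from_pairs(ids, seqs, ids2, seqs2)
    if pairing == "interleaved":
        if len(ids) % 2:
            raise ValueError(f"interleaved file has an odd record count ({len(ids)})")
        return ReadSet.from_pairs(ids[0::2], seqs[0::2], ids[1::2], seqs[1::2])
    raise ValueError(f"unknown pairing mode {pairing!r}")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    ids, seqs, _ = _parse_file(path, "fasta")
    return list(zip(ids, seqs))


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str | Path, ids: Iterable[str], seqs: Iterable[str], qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in zip(ids, seqs):
            fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    """TSV with a '#'-prefixed header line, no quoting."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected a '#'-prefixed header line")
        cols = header[1:].split("\t")
        df = pd.read_csv(fh, sep="\t", names=cols, header=None)
    return df


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(outdir: str | Path, files: Iterable[str | Path], extra: dict | None = None) -> Path:
    """Write manifest.json listing every output file with its checksum."""
    outdir = Path(outdir)
    entries = [
        {"path": str(Path(f).relative_to(outdir)), "sha256": sha256_of(f)}
        for f in sorted(map(str, files))
    ]
    manifest = {"files": entries}
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
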