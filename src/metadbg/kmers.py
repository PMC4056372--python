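"""Canonical k-mer encoding and extraction.

A k-mer is a DNA word of fixed odd length k over {A,C,G,T}.  Internally every
k-mer is packed into a 64-bit integer, two bits per base (A=0, C=1, G=2, T=3),
so equality, hashing and ordering operate on the packed form.  Because the
2-bit code preserves alphabetical order, numeric comparison of packed words is
identical to lexicographic comparison of the strings.

The *canonical* form of a k-mer is the lexicographically smaller of the word
and its reverse complement.  Restricting k to odd values guarantees that no
word equals its own reverse complement, so the strand flag is always well
defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "Kmer",
    "canonical_kmer",
    "extract_kmers",
    "revcomp",
    "encode_sequence",
    "decode_code",
]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: maximum k such that a word fits in an unsigned 64-bit integer
MAX_K = 31

# byte -> 2-bit code lookup; 255 marks anything that is not A/C/G/T.
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def _check_k(k: int) -> None:
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    if k > MAX_K:
        raise ValueError(f"k={k} exceeds the supported maximum of {MAX_K}")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 array (A=0,C=1,G=2,T=3, 255=other).

    Lowercase (soft-masked) input is accepted; ambiguity codes map to 255 and
    simply invalidate the windows that contain them.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode_code(code: int, k: int) -> str:
    """Unpack a 2-bit-encoded word back to its string form."""
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_BASES[(int(code) >> shift) & 3])
    return "".join(out)


def _codes_from_u8(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All length-k window codes of an encoded sequence.

    Returns ``(codes, valid)`` of length ``len(enc) - k + 1`` (empty for short
    input); ``valid`` is False for windows containing a non-ACGT symbol.
    """
    n = enc.size - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    bad = (enc > 3).astype(np.int32)
    # windows with any invalid base: sliding sum of `bad`
    cums = np.concatenate(([0], np.cumsum(bad)))
    valid = (cums[k:] - cums[:-k]) == 0
    clean = np.where(enc > 3, 0, enc).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | clean[j : j + n]
    return codes, valid


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of packed words."""
    mask = np.uint64((1 << (2 * k)) - 1)
    x = (~codes) & mask  # complement: b -> 3-b on every 2-bit group
    rc = np.zeros_like(codes)
    for _ in range(k):
        rc = (rc << np.uint64(2)) | (x & np.uint64(3))
        x = x >> np.uint64(2)
    return rc


def _canonical_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonicalise packed words; returns (canonical codes, forward flags)."""
    rc = _revcomp_codes(codes, k)
    fwd = codes <= rc
    return np.where(fwd, codes, rc), fwd


def _revcomp_code1(code: int, k: int) -> int:
    mask = (1 << (2 * k)) - 1
    x = (~code) & mask
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (x & 3)
        x >>= 2
    return rc


@dataclass(frozen=True, order=True)
class Kmer:
    """A packed DNA word of odd length k.

    Equality, hashing and ordering are on the 2-bit packed integer, which
    coincides with lexicographic order on the string form.
    """

    code: int
    k: int

    @property
    def word(self) -> str:
        return decode_code(self.code, self.k)

    def revcomp(self) -> "Kmer":
        return Kmer(_revcomp_code1(self.code, self.k), self.k)

    def is_canonical(self) -> bool:
        return self.code <= _revcomp_code1(self.code, self.k)

    def canonical(self) -> "Kmer":
        rc = _revcomp_code1(self.code, self.k)
        return self if self.code <= rc else Kmer(rc, self.k)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.word


def canonical_kmer(word: str) -> tuple[Kmer, bool]:
    """Canonicalise a single word.

    Returns ``(kmer, forward)`` where ``forward`` is True when the input was
    already the canonical strand.  Rejects non-ACGT characters (reporting the
    offending position) and even k.
    """
    k = len(word)
    _check_k(k)
    enc = encode_sequence(word)
    bad = np.nonzero(enc > 3)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"invalid nucleotide {word[pos]!r} at position {pos}; expected A/C/G/T"
        )
    code = 0
    for b in enc:
        code = (code << 2) | int(b)
    rc = _revcomp_code1(code, k)
    if code <= rc:
        return Kmer(code, k), True
    return Kmer(rc, k), False


def extract_kmers(sequence: str, k: int) -> list[tuple[Kmer, bool, int]]:
    """All canonical k-mers of a sequence as ``(kmer, forward, offset)``.

    Windows containing any non-ACGT symbol are skipped; offsets are 0-based on
    the input.  A sequence shorter than k yields an empty list.
    """
    _check_k(k)
    enc = encode_sequence(sequence)
    codes, valid = _codes_from_u8(enc, k)
    canon, fwd = _canonical_codes(codes, k)
    return [
        (Kmer(int(canon[i]), k), bool(fwd[i]), i)
        for i in np.nonzero(valid)[0]
    ]


def iter_clean_windows(sequence: str, k: int) -> Iterator[tuple[int, str]]:
    """Yield (offset, window) for every all-ACGT window of length k."""
    _check_k(k)
    enc = encode_sequence(sequence)
    codes, valid = _codes_from_u8(enc, k)
    for i in np.nonzero(valid)[0]:
        yield int(i), decode_code(int(codes[i]), k)
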