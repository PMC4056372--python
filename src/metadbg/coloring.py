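"""Graph coloring with reference sequences grouped in namespaces.

A *color* labels every graph k-mer that occurs in one reference sequence.
Colors are global integer ids; each belongs to exactly one namespace
(e.g. whole genomes for abundance estimation, coding sequences for ontology
profiling), and k-mer uniqueness is always judged within a single namespace.
Coloring never touches topology or coverage: assembly is independent of it.
Color sets are interned, so the number of stored set objects is bounded by
the number of distinct combinations encountered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .graph import DeBruijnGraph
from .kmers import Kmer, _canonical_codes, _codes_from_u8, canonical_kmer, encode_sequence

__all__ = ["ReferenceInfo", "ColorRegistry", "color_graph", "color_class", "assembly_overlap"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceInfo:
    color: int
    name: str
    length: int
    taxon_id: int | None = None
    go_terms: tuple[str, ...] = ()


class ColorRegistry:
    """Namespace -> color id -> reference bookkeeping.

    Registration is idempotent per (namespace, reference name), so coloring
    the same reference set twice changes nothing.
    """

    def __init__(self):
        self._namespaces: dict[str, dict[int, ReferenceInfo]] = {}
        self._by_name: dict[tuple[str, str], int] = {}
        self._color_ns: dict[int, str] = {}
        self._next = 0

    def add_namespace(self, namespace: str) -> None:
        self._namespaces.setdefault(namespace, {})

    @property
    def namespaces(self) -> list[str]:
        return list(self._namespaces)

    def register(
        self,
        namespace: str,
        name: str,
        length: int,
        taxon_id: int | None = None,
        go_terms: tuple[str, ...] = (),
    ) -> int:
        self.add_namespace(namespace)
        key = (namespace, name)
        if key in self._by_name:
            return self._by_name[key]
        color = self._next
        self._next += 1
        self._namespaces[namespace][color] = ReferenceInfo(
            color=color, name=name, length=length, taxon_id=taxon_id, go_terms=go_terms
        )
        self._by_name[key] = color
        self._color_ns[color] = namespace
        return color

    def colors_in(self, namespace: str) -> dict[int, ReferenceInfo]:
        if namespace not in self._namespaces:
            raise KeyError(f"unknown namespace {namespace!r}")
        return self._namespaces[namespace]

    def info(self, color: int) -> ReferenceInfo:
        return self._namespaces[self._color_ns[color]][color]


def _reference_canonical_codes(seq: str, k: int) -> np.ndarray:
    enc = encode_sequence(seq)
    codes, valid = _codes_from_u8(enc, k)
    canon, _ = _canonical_codes(codes, k)
    return np.unique(canon[valid])


def color_graph(
    graph: DeBruijnGraph,
    references: Iterable[tuple[str, str]],
    namespace: str,
    registry: ColorRegistry,
    taxon_map: Mapping[str, int] | None = None,
    go_map: Mapping[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Color pre-existing graph vertices with each reference's k-mers.

    Only vertices already in the graph receive colors; topology and coverage
    are untouched.  Returns a per-reference report with distinct k-mer counts
    and the matched fraction.
    """
    rows = []
    for name, seq in references:
        color = registry.register(
            namespace,
            name,
            length=len(seq),
            taxon_id=None if taxon_map is None else taxon_map.get(name),
            go_terms=() if go_map is None else tuple(go_map.get(name, ())),
        )
        codes = _reference_canonical_codes(seq, graph.k)
        if codes.size == 0:
            log.warning("reference %s is shorter than k=%d; 0 k-mers colored", name, graph.k)
            rows.append((namespace, name, color, 0, 0, 0.0))
            continue
        gids = graph.lookup(codes)
        hit = gids[gids >= 0]
        graph.add_color(hit, color)
        rows.append(
            (namespace, name, color, int(codes.size), int(hit.size), hit.size / codes.size)
        )
    return pd.DataFrame(
        rows,
        columns=["namespace", "reference", "color", "kmers_total", "kmers_matched", "fraction"],
    )


def color_class(
    graph: DeBruijnGraph, kmer: Kmer | str, namespace: str, registry: ColorRegistry
) -> tuple[str, frozenset[int]]:
    """Classify a vertex within one namespace.

    Returns ``("uncolored", {})``, ``("unique", {c})`` or
    ``("shared", {c1, c2, ...})``.  A k-mer carrying exactly one color in the
    namespace is specific to that one reference.
    """
    ns_colors = set(registry.colors_in(namespace))
    gid = graph.gid_of(kmer)
    if gid < 0:
        raise KeyError(f"k-mer not present in graph: {kmer}")
    colors = frozenset(c for c in graph.colors_of(gid) if c in ns_colors)
    if not colors:
        return "uncolored", colors
    if len(colors) == 1:
        return "unique", colors
    return "shared", colors


def _covered_bases(seq: str, k: int, other_codes: np.ndarray) -> int:
    """Bases of `seq` covered by >=1 window whose canonical k-mer is in `other_codes`."""
    enc = encode_sequence(seq)
    codes, valid = _codes_from_u8(enc, k)
    if codes.size == 0:
        return 0
    canon, _ = _canonical_codes(codes, k)
    pos = np.searchsorted(other_codes, canon)
    pos_c = np.minimum(pos, max(other_codes.size - 1, 0))
    hit = valid & (other_codes.size > 0) & (other_codes[pos_c] == canon)
    starts = np.flatnonzero(hit)
    if starts.size == 0:
        return 0
    diff = np.zeros(len(seq) + 1, dtype=np.int32)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + k, -1)
    return int(np.count_nonzero(np.cumsum(diff[:-1]) > 0))


def assembly_overlap(
    assembly_a: Iterable[tuple[str, str]],
    assembly_b: Iterable[tuple[str, str]],
    k: int,
    min_len: int = 500,
) -> dict[str, int]:
    """Shared nucleotide totals between two assemblies, both directions.

    A base of an assembly-A sequence (length >= min_len) counts as shared when
    at least one k-length window covering it has its canonical k-mer somewhere
    in assembly B (B filtered to >= min_len as well); no mismatches are
    tolerated within a window.  The symmetric direction is reported too.
    """
    a = [(n, s) for n, s in assembly_a if len(s) >= min_len]
    b = [(n, s) for n, s in assembly_b if len(s) >= min_len]

    def codes_of(side: list[tuple[str, str]]) -> np.ndarray:
        if not side:
            return np.empty(0, dtype=np.uint64)
        parts = [_reference_canonical_codes(s, k) for _, s in side]
        return np.unique(np.concatenate(parts))

    b_codes = codes_of(b)
    a_codes = codes_of(a)
    a_shared = sum(_covered_bases(s, k, b_codes) for _, s in a)
    b_shared = sum(_covered_bases(s, k, a_codes) for _, s in b)
    return {
        "a_shared": a_shared,
        "a_total": sum(len(s) for _, s in a),
        "b_shared": b_shared,
        "b_total": sum(len(s) for _, s in b),
    }
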