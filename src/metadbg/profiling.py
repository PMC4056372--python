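"""Abundance, taxonomic and gene-ontology profiles from a colored graph.

The abundance currency throughout is the *k-mer observation*: one unit of
coverage depth on a colored k-mer.  Reference proportions are estimated by
demultiplexing coverage through uniquely-colored k-mers: for reference c,

    observations(c) = matched(c) * mode_u(c)

where matched(c) is the number of distinct graph k-mers carrying color c and
mode_u(c) is the modal coverage of the k-mers colored exactly {c} within the
namespace (ties broken toward the smaller value).  The total is the sum of
coverage over all colored k-mers, and a proportion is observations / total.
A reference with no uniquely-colored k-mer (e.g. a genome registered twice)
gets proportion 0 and a "no-unique-kmers" flag.

Taxonomic profiles classify each colored k-mer at the nearest common ancestor
of the taxa its colors map to, crediting the vertex's full coverage there;
per-rank reports aggregate subtree sums plus an unclassified-at-rank bucket,
which keeps the observation total exactly conserved.  Ontology profiles add
each colored vertex's coverage once to every distinct GO term annotated on
its colors (flat counting; no DAG up-propagation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coloring import ColorRegistry
from .graph import DeBruijnGraph

__all__ = [
    "RANKS",
    "TaxonomyTree",
    "lca_assign",
    "reference_proportions",
    "taxonomic_profile",
    "ontology_profile",
    "biom_export",
]

log = logging.getLogger(__name__)

RANKS = ["root", "kingdom", "phylum", "class", "order", "family", "genus", "species"]
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


@dataclass
class TaxonomyTree:
    """Rooted tree of taxa over the seven standard ranks (plus root).

    ``color_map`` attaches graph colors to nodes so LCA queries can be
    answered for color sets.
    """

    parent: dict[int, int]  # node -> parent (root maps to itself)
    rank: dict[int, str]
    name: dict[int, str]
    root: int
    color_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self._depth: dict[int, int] = {self.root: 0}
        self.children: dict[int, list[int]] = {n: [] for n in self.parent}
        for n, p in self.parent.items():
            if n != self.root:
                self.children[p].append(n)
        # iterative depth computation; also validates connectivity and ranks
        stack = [self.root]
        seen = 1
        while stack:
            cur = stack.pop()
            for ch in self.children[cur]:
                if _RANK_INDEX[self.rank[ch]] <= _RANK_INDEX[self.rank[cur]]:
                    raise ValueError(
                        f"rank order violated: {self.rank[ch]} node {ch} under "
                        f"{self.rank[cur]} node {cur}"
                    )
                self._depth[ch] = self._depth[cur] + 1
                stack.append(ch)
                seen += 1
        if seen != len(self.parent):
            raise ValueError("taxonomy is not a single rooted tree")

    # -------------------------------------------------------------- builders

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaxonomyTree":
        """Build from rows (node_id, parent_id, rank, name); parent 0 or self marks the root."""
        parent: dict[int, int] = {}
        rank: dict[int, str] = {}
        name: dict[int, str] = {}
        roots = []
        for row in df.itertuples(index=False):
            nid, pid = int(row.node_id), int(row.parent_id)
            if pid == 0 or pid == nid:
                pid = nid
                roots.append(nid)
            parent[nid] = pid
            rank[nid] = str(row.rank)
            name[nid] = str(row.name)
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        return cls(parent=parent, rank=rank, name=name, root=roots[0])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        from .io import read_table

        return cls.from_frame(read_table(path))

    @classmethod
    def from_lineages(cls, lineages: dict[str, str]) -> "TaxonomyTree":
        """Build from Greengenes-style lineage strings.

        ``lineages`` maps a leaf label to a string like
        ``"k__Bacteria;p__Firmicutes;...;s__"``; empty fields are skipped and
        the leaf is attached below the last non-empty level as a species node
        named after the label when no ``s__`` field is given.
        """
        prefix_rank = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
                       "f": "family", "g": "genus", "s": "species"}
        parent = {1: 1}
        rank = {1: "root"}
        name = {1: "root"}
        index: dict[tuple[int, str, str], int] = {}
        nxt = 2

        def child(par: int, rk: str, nm: str) -> int:
            nonlocal nxt
            key = (par, rk, nm)
            if key not in index:
                index[key] = nxt
                parent[nxt] = par
                rank[nxt] = rk
                name[nxt] = nm
                nxt += 1
            return index[key]

        tree = None
        leaves: dict[str, int] = {}
        for label, lineage in lineages.items():
            cur = 1
            had_species = False
            for fieldstr in lineage.split(";"):
                fieldstr = fieldstr.strip()
                if not fieldstr or "__" not in fieldstr:
                    continue
                pfx, val = fieldstr.split("__", 1)
                if not val:
                    continue
                rk = prefix_rank[pfx.strip()]
                cur = child(cur, rk, val)
                had_species = had_species or rk == "species"
            if not had_species:
                cur = child(cur, "species", label)
            leaves[label] = cur
        tree = cls(parent=parent, rank=rank, name=name, root=1)
        tree.leaf_of = leaves  # type: ignore[attr-defined]
        return tree

    # --------------------------------------------------------------- queries

    def depth(self, node: int) -> int:
        return self._depth[node]

    def ancestors(self, node: int) -> list[int]:
        """Path from the root down to (and including) the node."""
        path = [node]
        while node != self.root:
            node = self.parent[node]
            path.append(node)
        return path[::-1]

    def lca(self, nodes: list[int]) -> int:
        """Deepest node ancestral to (or equal to) all given nodes."""
        if not nodes:
            raise ValueError("lca of an empty node set")
        cur = nodes[0]
        for other in nodes[1:]:
            a, b = cur, other
            while self._depth[a] > self._depth[b]:
                a = self.parent[a]
            while self._depth[b] > self._depth[a]:
                b = self.parent[b]
            while a != b:
                a = self.parent[a]
                b = self.parent[b]
            cur = a
        return cur

    def set_color_map(self, mapping: dict[int, int]) -> None:
        for color, node in mapping.items():
            if node not in self.parent:
                raise ValueError(f"color {color} maps to unknown taxon {node}")
        self.color_map = dict(mapping)

    def map_colors_by_name(self, registry: ColorRegistry, namespace: str, ref_taxon: pd.DataFrame) -> None:
        """Fill color_map from a (reference, taxon_id) table via the registry."""
        by_name = {str(r.reference): int(r.taxon_id) for r in ref_taxon.itertuples(index=False)}
        mapping = {}
        for color, info in registry.colors_in(namespace).items():
            if info.name in by_name:
                mapping[color] = by_name[info.name]
        self.set_color_map(mapping)


def lca_assign(colors: frozenset[int] | set[int], taxonomy: TaxonomyTree) -> int:
    """Taxon for a color set: the node itself for one color, else the LCA."""
    nodes = []
    for c in sorted(colors):
        if c not in taxonomy.color_map:
            raise KeyError(f"color {c} has no taxon mapping")
        nodes.append(taxonomy.color_map[c])
    return taxonomy.lca(nodes)


# ---------------------------------------------------------------- internals


def _namespace_sets(graph: DeBruijnGraph, namespace: str, registry: ColorRegistry):
    """Per interned color-set id: the tuple of its colors inside the namespace.

    Returns (sid_colors list, sid_of_vertex array, coverage array).
    """
    ns = set(registry.colors_in(namespace))
    sid_colors = [tuple(sorted(c for c in s if c in ns)) for s in graph.colorsets]
    return sid_colors, graph.colorset_id, graph.coverage.astype(np.int64)


def _sid_aggregates(sid_of_vertex: np.ndarray, coverage: np.ndarray, n_sets: int):
    """Vertex count and coverage sum per interned set id (colored vertices only)."""
    mask = sid_of_vertex >= 0
    sids = sid_of_vertex[mask]
    counts = np.bincount(sids, minlength=n_sets).astype(np.int64)
    cov_sums = np.bincount(sids, weights=coverage[mask], minlength=n_sets).astype(np.int64)
    return counts, cov_sums


# ------------------------------------------------------------------ profiles


def reference_proportions(
    graph: DeBruijnGraph, namespace: str, registry: ColorRegistry
) -> pd.DataFrame:
    """Demultiplexed per-reference abundance table.

    Columns: color, reference, matched (distinct k-mers carrying the color),
    unique_kmers, mode_unique, observations, total, proportion, flag.
    """
    sid_colors, sid_of_vertex, coverage = _namespace_sets(graph, namespace, registry)
    counts, cov_sums = _sid_aggregates(sid_of_vertex, coverage, len(sid_colors))
    total = int(sum(cs for sc, cs in zip(sid_colors, cov_sums) if sc))
    refs = registry.colors_in(namespace)
    if total == 0:
        log.warning("namespace %r has no colored k-mer observations", namespace)
        return pd.DataFrame(
            columns=["color", "reference", "matched", "unique_kmers", "mode_unique",
                     "observations", "total", "proportion", "flag"]
        )

    matched = {c: 0 for c in refs}
    for sid, sc in enumerate(sid_colors):
        for c in sc:
            matched[c] += int(counts[sid])

    rows = []
    for color in sorted(refs):
        unique_sids = [
            sid for sid, sc in enumerate(sid_colors) if sc == (color,) and counts[sid] > 0
        ]
        if unique_sids:
            sel = np.isin(sid_of_vertex, unique_sids)
            covs = coverage[sel]
            vals, vcounts = np.unique(covs, return_counts=True)
            # modal coverage; ties break toward the smaller value (np.unique
            # returns ascending values, argmax takes the first maximum)
            mode_u = int(vals[np.argmax(vcounts)])
            n_unique = int(covs.size)
            obs = matched[color] * mode_u
            flag = ""
        else:
            mode_u = 0
            n_unique = 0
            obs = 0
            flag = "no-unique-kmers"
        rows.append(
            (color, refs[color].name, matched[color], n_unique, mode_u, obs, total,
             obs / total, flag)
        )
    return pd.DataFrame(
        rows,
        columns=["color", "reference", "matched", "unique_kmers", "mode_unique",
                 "observations", "total", "proportion", "flag"],
    )


def taxonomic_profile(
    graph: DeBruijnGraph,
    taxonomy: TaxonomyTree,
    namespace: str,
    registry: ColorRegistry,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Coverage-weighted taxon assignments plus per-rank rollups.

    Every colored vertex contributes its full coverage to the LCA of its
    color set.  The node table reports directly-assigned observations; each
    rank table reports subtree sums for that rank's nodes plus an
    "unclassified at this rank" bucket for observations assigned above it.
    The sum of directly-assigned observations equals the total colored
    coverage exactly.
    """
    sid_colors, sid_of_vertex, coverage = _namespace_sets(graph, namespace, registry)
    _, cov_sums = _sid_aggregates(sid_of_vertex, coverage, len(sid_colors))

    node_obs: dict[int, int] = {}
    total = 0
    for sid, sc in enumerate(sid_colors):
        if not sc or cov_sums[sid] == 0:
            continue
        node = lca_assign(frozenset(sc), taxonomy)
        node_obs[node] = node_obs.get(node, 0) + int(cov_sums[sid])
        total += int(cov_sums[sid])

    node_rows = [
        (n, taxonomy.name[n], taxonomy.rank[n], obs, obs / total if total else 0.0)
        for n, obs in sorted(node_obs.items())
    ]
    node_table = pd.DataFrame(
        node_rows, columns=["node_id", "name", "rank", "observations", "proportion"]
    )

    rank_tables: dict[str, pd.DataFrame] = {}
    for r in RANKS[1:]:
        r_idx = _RANK_INDEX[r]
        bucket: dict[int, int] = {}
        unclassified = 0
        for node, obs in node_obs.items():
            anc = None
            for a in taxonomy.ancestors(node):
                if _RANK_INDEX[taxonomy.rank[a]] == r_idx:
                    anc = a
                    break
            if anc is None:
                unclassified += obs  # assigned above this rank
            else:
                bucket[anc] = bucket.get(anc, 0) + obs
        rows = [
            (n, taxonomy.name[n], obs, obs / total if total else 0.0)
            for n, obs in sorted(bucket.items())
        ]
        rows.append((-1, "unclassified", unclassified, unclassified / total if total else 0.0))
        rank_tables[r] = pd.DataFrame(
            rows, columns=["node_id", "name", "observations", "proportion"]
        )
    return node_table, rank_tables


@dataclass
class OntologyProfile:
    per_domain: dict[str, pd.DataFrame]
    unannotated: int
    total: int


def ontology_profile(
    graph: DeBruijnGraph,
    namespace: str,
    registry: ColorRegistry,
    domains: dict[str, str],
) -> OntologyProfile:
    """Per-GO-term observation totals, grouped by ontology domain.

    ``domains`` maps a GO id to its domain name.  Each colored vertex adds
    its coverage once to every distinct term among its colors' annotations;
    vertices whose colors carry no annotation at all are tallied in an
    "unannotated" bucket.
    """
    sid_colors, sid_of_vertex, coverage = _namespace_sets(graph, namespace, registry)
    _, cov_sums = _sid_aggregates(sid_of_vertex, coverage, len(sid_colors))

    term_obs: dict[str, int] = {}
    unannotated = 0
    total = 0
    for sid, sc in enumerate(sid_colors):
        if not sc or cov_sums[sid] == 0:
            continue
        cov = int(cov_sums[sid])
        total += cov
        terms = set()
        for c in sc:
            terms.update(registry.info(c).go_terms)
        if not terms:
            unannotated += cov
            continue
        for t in terms:
            term_obs[t] = term_obs.get(t, 0) + cov

    per_domain: dict[str, pd.DataFrame] = {}
    for dom in sorted(set(domains.values())):
        rows = [
            (t, obs, obs / total if total else 0.0)
            for t, obs in term_obs.items()
            if domains.get(t) == dom
        ]
        rows.sort(key=lambda r: (-r[1], r[0]))
        per_domain[dom] = pd.DataFrame(rows, columns=["go_id", "observations", "proportion"])
    return OntologyProfile(per_domain=per_domain, unannotated=unannotated, total=total)


def biom_export(table: pd.DataFrame, id_col: str, value_col: str, table_id: str) -> dict:
    """Minimal BIOM-style (v1, dense) JSON payload for one profile table."""
    ids = [str(v) for v in table[id_col]]
    data = [[float(v)] for v in table[value_col]]
    return {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "type": "Taxon table",
        "matrix_type": "dense",
        "matrix_element_type": "float",
        "shape": [len(ids), 1],
        "rows": [{"id": i, "metadata": None} for i in ids],
        "columns": [{"id": table_id, "metadata": None}],
        "data": data,
    }
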