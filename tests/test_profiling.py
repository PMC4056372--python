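"""Reference proportions, LCA taxonomy and GO profiles."""

import numpy as np
import pandas as pd
import pytest

from metadbg.coloring import ColorRegistry, color_graph
from metadbg.graph import build_graph
from metadbg.profiling import (
    RANKS,
    TaxonomyTree,
    lca_assign,
    ontology_profile,
    reference_proportions,
    taxonomic_profile,
)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def chop(seq, length=45, step=1):
    return [seq[i : i + length] for i in range(0, len(seq) - length + 1, step)]


def make_tree(rows):
    return TaxonomyTree.from_frame(
        pd.DataFrame(rows, columns=["node_id", "parent_id", "rank", "name"])
    )


@pytest.fixture
def small_tree():
    # root -> kingdom K1,K2; K1 -> genus G (rank skipping allowed) -> species A,B
    return make_tree(
        [
            (1, 0, "root", "root"),
            (2, 1, "kingdom", "K1"),
            (3, 1, "kingdom", "K2"),
            (4, 2, "genus", "G"),
            (5, 4, "species", "A"),
            (6, 4, "species", "B"),
            (7, 3, "species", "C"),
        ]
    )


# --------------------------------------------------------------------- LCA


def test_lca_examples(small_tree):
    small_tree.set_color_map({10: 5, 11: 6, 12: 7})
    assert lca_assign({10}, small_tree) == 5  # single color -> its node
    assert lca_assign({10, 11}, small_tree) == 4  # siblings -> genus
    assert lca_assign({10, 12}, small_tree) == 1  # across kingdoms -> root
    with pytest.raises(KeyError, match="99"):
        lca_assign({99}, small_tree)


def brute_force_lca(tree, nodes):
    paths = [tree.ancestors(n) for n in nodes]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    return max(common, key=tree.depth)


def test_lca_matches_bruteforce_on_random_taxonomy():
    """1,000 random color sets on a random 50-node taxonomy match the
    root-path-intersection oracle in every case."""
    rng = np.random.default_rng(1234)
    rows = [(1, 0, "root", "root")]
    for nid in range(2, 51):
        parent = int(rng.integers(1, nid))
        prank = rows[parent - 1][2]
        pidx = RANKS.index(prank)
        if pidx >= len(RANKS) - 1:
            parent = 1
            pidx = 0
        rank = RANKS[int(rng.integers(pidx + 1, len(RANKS)))]
        rows.append((nid, parent, rank, f"n{nid}"))
    tree = make_tree(rows)
    tree.set_color_map({c: c + 1 for c in range(50)})
    for _ in range(1000):
        size = int(rng.integers(1, 6))
        colors = set(int(c) for c in rng.integers(0, 50, size))
        nodes = [tree.color_map[c] for c in sorted(colors)]
        assert lca_assign(colors, tree) == brute_force_lca(tree, nodes)


def test_tree_validation():
    with pytest.raises(ValueError, match="root"):
        make_tree([(1, 0, "root", "r"), (2, 0, "root", "r2")])
    with pytest.raises(ValueError, match="rank order"):
        make_tree([(1, 0, "root", "r"), (2, 1, "species", "s"), (3, 2, "genus", "g")])


def test_greengenes_lineage_converter():
    tree = TaxonomyTree.from_lineages(
        {
            "x": "k__Bacteria;p__Firmicutes;c__;o__;f__;g__Bacillus;s__subtilis",
            "y": "k__Bacteria;p__Firmicutes;c__;o__;f__;g__Bacillus;s__cereus",
            "z": "k__Bacteria;p__Bacteroidetes",
        }
    )
    lx, ly, lz = tree.leaf_of["x"], tree.leaf_of["y"], tree.leaf_of["z"]
    assert tree.rank[lx] == "species"
    assert tree.parent[lx] == tree.parent[ly]  # shared genus
    assert tree.rank[lz] == "species" and tree.name[lz] == "z"
    assert tree.lca([lx, lz]) == tree.parent[tree.parent[lx]] or tree.rank[tree.lca([lx, lz])] == "kingdom"


# -------------------------------------------------------------- proportions


def colored_toy(rng_seed=3, n1=400, n2=300, c1=4, c2=2):
    """Two disjoint random genomes at controlled uniform coverages."""
    rng = np.random.default_rng(rng_seed)
    g1 = random_dna(rng, n1)
    g2 = random_dna(rng, n2)
    reads = chop(g1) * c1 + chop(g2) * c2
    g = build_graph(reads, 31)
    reg = ColorRegistry()
    color_graph(g, [("r1", g1), ("r2", g2)], "genomes", reg)
    return g, reg, g1, g2


def test_single_reference_proportion_one():
    rng = np.random.default_rng(8)
    genome = random_dna(rng, 500)
    g = build_graph([genome] * 3, 31)  # uniform coverage 3 on every vertex
    reg = ColorRegistry()
    color_graph(g, [("only", genome)], "genomes", reg)
    t = reference_proportions(g, "genomes", reg)
    assert t.iloc[0]["proportion"] == 1.0
    n = len(g)
    assert t.iloc[0]["observations"] == n * 3


def test_two_disjoint_references_closed_form():
    g, reg, g1, g2 = colored_toy()
    t = reference_proportions(g, "genomes", reg).set_index("reference")
    # brute-force oracle over the graph itself
    total = 0
    obs = {}
    for gid in range(len(g)):
        colors = g.colors_of(gid)
        if colors:
            total += int(g.coverage[gid])
    for name in ("r1", "r2"):
        color = [c for c, i in reg.colors_in("genomes").items() if i.name == name][0]
        unique = [
            int(g.coverage[gid])
            for gid in range(len(g))
            if g.colors_of(gid) == frozenset({color})
        ]
        vals, counts = np.unique(unique, return_counts=True)
        mode = int(vals[np.argmax(counts)])
        matched = sum(1 for gid in range(len(g)) if color in g.colors_of(gid))
        obs[name] = matched * mode
    for name in ("r1", "r2"):
        assert t.loc[name, "observations"] == obs[name]
        assert t.loc[name, "proportion"] == pytest.approx(obs[name] / total)


def test_mode_tie_breaks_low():
    # uniform artificial coverage multiset {3,3,4,4} -> mode 3
    vals = np.array([3, 4, 4, 3])
    u, c = np.unique(vals, return_counts=True)
    assert int(u[np.argmax(c)]) == 3


def test_duplicate_reference_zero_proportion_flagged():
    rng = np.random.default_rng(21)
    genome = random_dna(rng, 400)
    g = build_graph(chop(genome) * 2, 31)
    reg = ColorRegistry()
    color_graph(g, [("a", genome), ("a_copy", genome)], "genomes", reg)
    t = reference_proportions(g, "genomes", reg)
    assert list(t["proportion"]) == [0.0, 0.0]
    assert list(t["flag"]) == ["no-unique-kmers"] * 2


def test_empty_namespace_gives_empty_table():
    g = build_graph(["ACGTACGTAGCTAGCATCGAT"], 5)
    reg = ColorRegistry()
    reg.add_namespace("genomes")
    t = reference_proportions(g, "genomes", reg)
    assert t.empty


# ---------------------------------------------------------------- taxonomy


def test_taxonomic_profile_hand_example(small_tree):
    """10 vertices cov 2 unique to species A plus 5 vertices cov 4 shared A,B:
    A holds 20 direct observations, genus G holds 20, the genus-rank subtree
    for G is 40, and 20 observations are unclassified at species rank."""
    rng = np.random.default_rng(17)
    a_part = random_dna(rng, 40)  # 10 k-mers at k=31
    shared = random_dna(rng, 35)  # 5 k-mers
    reads = [a_part] * 2 + [shared] * 4
    g = build_graph(reads, 31)
    reg = ColorRegistry()
    ca = reg.register("genomes", "A", 40)
    cb = reg.register("genomes", "B", 35)
    color_graph(g, [("A", a_part), ("A", shared)], "genomes", reg)
    color_graph(g, [("B", shared)], "genomes", reg)
    small_tree.set_color_map({ca: 5, cb: 6})
    node_table, rank_tables = taxonomic_profile(g, small_tree, "genomes", reg)
    direct = dict(zip(node_table["node_id"], node_table["observations"]))
    assert direct == {5: 20, 4: 20}
    genus = rank_tables["genus"].set_index("node_id")
    assert genus.loc[4, "observations"] == 40
    species = rank_tables["species"].set_index("node_id")
    assert species.loc[5, "observations"] == 20
    assert species.loc[-1, "observations"] == 20  # unclassified at species rank


def test_conservation_exact(small_tree):
    rng = np.random.default_rng(30)
    g1 = random_dna(rng, 300)
    g2 = random_dna(rng, 300)
    reads = chop(g1) * 3 + chop(g2) * 2
    g = build_graph(reads, 31)
    reg = ColorRegistry()
    color_graph(g, [("A", g1), ("B", g2)], "genomes", reg)
    colors = {i.name: c for c, i in reg.colors_in("genomes").items()}
    small_tree.set_color_map({colors["A"]: 5, colors["B"]: 6})
    node_table, rank_tables = taxonomic_profile(g, small_tree, "genomes", reg)
    colored_cov = sum(
        int(g.coverage[gid]) for gid in range(len(g)) if g.colors_of(gid)
    )
    assert int(node_table["observations"].sum()) == colored_cov
    # every rank conserves: subtree sums + unclassified == total
    for r, tab in rank_tables.items():
        assert int(tab["observations"].sum()) == colored_cov


def test_rank_monotonicity(small_tree):
    rng = np.random.default_rng(31)
    g1, g2 = random_dna(rng, 200), random_dna(rng, 200)
    g = build_graph(chop(g1) + chop(g2), 31)
    reg = ColorRegistry()
    color_graph(g, [("A", g1), ("B", g2)], "genomes", reg)
    colors = {i.name: c for c, i in reg.colors_in("genomes").items()}
    small_tree.set_color_map({colors["A"]: 5, colors["B"]: 6})
    _, rank_tables = taxonomic_profile(g, small_tree, "genomes", reg)
    genus = rank_tables["genus"].set_index("node_id")["observations"]
    species = rank_tables["species"].set_index("node_id")["observations"]
    for sp, parent in ((5, 4), (6, 4)):
        if sp in species.index and parent in genus.index:
            assert genus.loc[parent] >= species.loc[sp]


# ---------------------------------------------------------------------- GO


def go_setup(cds_terms):
    """Color one graph with CDS references carrying the given GO annotations."""
    rng = np.random.default_rng(40)
    seqs = {name: random_dna(rng, 120) for name in cds_terms}
    reads = [s for s in seqs.values() for _ in range(2)]
    g = build_graph(reads, 31)
    reg = ColorRegistry()
    color_graph(
        g,
        list(seqs.items()),
        "cds",
        reg,
        go_map={n: tuple(t) for n, t in cds_terms.items()},
    )
    return g, reg, seqs


def test_single_cds_single_term():
    g, reg, seqs = go_setup({"cds1": ["GO:1"]})
    prof = ontology_profile(g, "cds", reg, {"GO:1": "biological_process"})
    tab = prof.per_domain["biological_process"]
    m = len(seqs["cds1"]) - 31 + 1
    assert tab.iloc[0]["observations"] == 2 * m


def test_shared_term_counted_once_per_vertex():
    """Two CDS sharing a term on the same vertex credit the term once."""
    rng = np.random.default_rng(41)
    s = random_dna(rng, 100)
    g = build_graph([s, s], 31)
    reg = ColorRegistry()
    color_graph(g, [("c1", s), ("c2", s)], "cds", reg, go_map={"c1": ("GO:1",), "c2": ("GO:1",)})
    prof = ontology_profile(g, "cds", reg, {"GO:1": "molecular_function"})
    # brute-force oracle over vertices and terms
    expected = sum(int(g.coverage[gid]) for gid in range(len(g)) if g.colors_of(gid))
    assert prof.per_domain["molecular_function"].iloc[0]["observations"] == expected


def test_distinct_terms_both_credited():
    rng = np.random.default_rng(42)
    s = random_dna(rng, 100)
    g = build_graph([s], 31)
    reg = ColorRegistry()
    color_graph(g, [("c1", s), ("c2", s)], "cds", reg, go_map={"c1": ("GO:1",), "c2": ("GO:2",)})
    prof = ontology_profile(
        g, "cds", reg, {"GO:1": "molecular_function", "GO:2": "biological_process"}
    )
    cov = sum(int(g.coverage[gid]) for gid in range(len(g)) if g.colors_of(gid))
    assert prof.per_domain["molecular_function"].iloc[0]["observations"] == cov
    assert prof.per_domain["biological_process"].iloc[0]["observations"] == cov


def test_unannotated_cds_bucket():
    g, reg, seqs = go_setup({"cds1": []})
    prof = ontology_profile(g, "cds", reg, {})
    assert prof.unannotated == prof.total > 0
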