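"""Supermatrix construction, quartet scoring against a four-point-condition
oracle, exact consensus search, bootstrap, and concordance factors."""

import random
from itertools import combinations

import dendropy
import numpy as np
import pytest

from phylomark import (
    Alphabet,
    Msa,
    SpeciesTreeError,
    bootstrap_support,
    concatenate,
    concordance_factors,
    consensus_species_tree,
    quartet_score,
    read_supported_newick,
    robinson_foulds,
    supermatrix_tree,
    write_supported_newick,
)
from phylomark.speciestree import (
    Supermatrix,
    gene_concordance,
    write_partitions,
    write_phylip,
)
from phylomark import trees as _t


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

def _msa(rows):
    return Msa(rows, Alphabet.AMINO20)


def test_concatenate_coordinates_and_order():
    m1 = _msa([(t, "AAA") for t in "abcd"])
    m2 = _msa([(t, "CCCCC") for t in "abcd"])
    sm = concatenate({"m2": m2, "m1": m1})
    assert sm.msa.length == 8
    assert sm.partitions == (("m1", 1, 3), ("m2", 4, 8))
    assert sm.msa.sequence("a") == "AAACCCCC"


def test_concatenate_gap_fills_missing_taxa():
    m1 = _msa([(t, "AAA") for t in "abcd"])
    m2 = _msa([(t, "CC") for t in "abc"])
    sm = concatenate({"m1": m1, "m2": m2})
    assert sm.msa.sequence("d") == "AAA--"


def test_single_marker_supermatrix_is_identity():
    m1 = _msa([(t, "ADEF") for t in "abcd"])
    sm = concatenate({"m1": m1})
    assert sm.msa.rows == m1.rows
    assert sm.partitions == (("m1", 1, 4),)


def test_concatenate_rejects_empty_input():
    with pytest.raises(SpeciesTreeError):
        concatenate({})


def test_interop_files(tmp_path):
    m1 = _msa([(t, "AAA") for t in "abcd"])
    m2 = _msa([(t, "CCCCC") for t in "abcd"])
    sm = concatenate({"m1": m1, "m2": m2})
    write_phylip(sm, tmp_path / "sm.phy")
    write_partitions(sm, tmp_path / "parts.txt")
    lines = (tmp_path / "sm.phy").read_text().splitlines()
    assert lines[0] == "4 8"
    assert (tmp_path / "parts.txt").read_text() == (
        "LG, m1 = 1-3\nLG, m2 = 4-8\n"
    )


# ---------------------------------------------------------------------------
# quartet scoring
# ---------------------------------------------------------------------------

def quartet_oracle(tree, labels4):
    """Induced quartet pairing via the four-point condition on edge counts."""
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    a, b, c, d = labels4

    def e(x, y):
        return pdm.path_edge_count(tax[x], tax[y])

    sums = {
        frozenset([frozenset([a, b]), frozenset([c, d])]): e(a, b) + e(c, d),
        frozenset([frozenset([a, c]), frozenset([b, d])]): e(a, c) + e(b, d),
        frozenset([frozenset([a, d]), frozenset([b, c])]): e(a, d) + e(b, c),
    }
    lo = min(sums.values())
    winners = [k for k, v in sums.items() if v == lo]
    return winners[0] if len(winners) == 1 else None


def bruteforce_quartet_score(species, gene_trees):
    total = 0
    for gt in gene_trees:
        labels = sorted(l.taxon.label for l in gt.leaf_node_iter())
        for four in combinations(labels, 4):
            rg = quartet_oracle(gt, four)
            if rg is not None and rg == quartet_oracle(species, four):
                total += 1
    return total


def test_identical_quartet_trees_score_fully():
    sp = _t.read_newick("((A,B),(C,D));")
    gts = [_t.read_newick("((A,B),(C,D));") for _ in range(3)]
    assert quartet_score(sp, gts) == 3


def test_conflicting_quartet_scores_zero():
    sp = _t.read_newick("((A,C),(B,D));")
    gts = [_t.read_newick("((A,B),(C,D));") for _ in range(3)]
    assert quartet_score(sp, gts) == 0


def test_quartet_score_matches_bruteforce_enumeration():
    rnd = random.Random(11)
    labels = [f"t{i}" for i in range(6)]
    species = _t.random_binary_tree(labels, rnd)
    gene_trees = [_t.random_binary_tree(labels, rnd) for _ in range(20)]
    assert quartet_score(species, gene_trees) == bruteforce_quartet_score(
        species, gene_trees
    )


def test_quartet_score_upper_bound_and_equality_condition():
    rnd = random.Random(5)
    labels = [f"t{i}" for i in range(6)]
    sp = _t.random_binary_tree(labels, rnd)
    same = [_t.read_newick(_t.to_newick(sp)) for _ in range(4)]
    nmax = 4 * 15  # 4 trees x C(6,4)
    assert quartet_score(sp, same) == nmax
    other = [_t.random_binary_tree(labels, rnd) for _ in range(4)]
    assert quartet_score(sp, other) < nmax


def test_quartet_score_rejects_unknown_taxa():
    sp = _t.read_newick("((A,B),(C,D));")
    gt = _t.read_newick("((A,B),(C,E));")
    with pytest.raises(SpeciesTreeError, match="absent"):
        quartet_score(sp, [gt])


def test_missing_taxa_quartets_are_skipped():
    sp = _t.read_newick("((A,B),(C,(D,E)));")
    gt = _t.read_newick("((A,B),(C,D));")  # lacks E: only 1 quartet counts
    assert quartet_score(sp, [gt, gt]) == 2


# ---------------------------------------------------------------------------
# consensus species tree
# ---------------------------------------------------------------------------

def all_topologies_dendropy(labels):
    """Independent enumerator: stepwise insertion on dendropy trees."""
    tns = dendropy.TaxonNamespace(sorted(labels))
    base = dendropy.Tree.get(
        data=f"({labels[0]},{labels[1]},{labels[2]});",
        schema="newick",
        taxon_namespace=tns,
    )
    trees = [base]
    for label in labels[3:]:
        nxt = []
        for tree in trees:
            edges = [
                e for e in tree.preorder_edge_iter() if e.tail_node is not None
            ]
            for i in range(len(edges)):
                clone = dendropy.Tree(tree)
                cedges = [
                    e for e in clone.preorder_edge_iter()
                    if e.tail_node is not None
                ]
                edge = cedges[i]
                parent, child = edge.tail_node, edge.head_node
                mid = dendropy.Node()
                parent.remove_child(child)
                parent.add_child(mid)
                mid.add_child(child)
                leaf = dendropy.Node(taxon=tns.get_taxon(label))
                mid.add_child(leaf)
                nxt.append(clone)
        trees = nxt
    for t in trees:
        t.is_rooted = False
    return trees


def test_unanimous_gene_trees_return_their_topology():
    rnd = random.Random(2)
    labels = [f"t{i}" for i in range(6)]
    topo = _t.random_binary_tree(labels, rnd)
    gts = [_t.read_newick(_t.to_newick(topo)) for _ in range(5)]
    cons = consensus_species_tree(gts)
    assert robinson_foulds(topo, cons)[0] == 0


def test_majority_topology_wins_exhaustive_search():
    t1 = "((A,B),(C,D),E);"
    t2 = "((A,C),(B,D),E);"
    gts = [_t.read_newick(t1) for _ in range(3)] + [
        _t.read_newick(t2) for _ in range(2)
    ]
    cons = consensus_species_tree(gts)
    assert robinson_foulds(_t.read_newick(t1), cons)[0] == 0


def test_exact_consensus_equals_bruteforce_argmax():
    """Consensus output attains the max quartet score over every topology."""
    rnd = random.Random(7)
    for n in (5, 6):
        labels = [f"t{i}" for i in range(n)]
        gts = [_t.random_binary_tree(labels, rnd) for _ in range(7)]
        cons = consensus_species_tree(gts)
        best = max(
            quartet_score(t, gts) for t in all_topologies_dendropy(labels)
        )
        assert quartet_score(cons, gts) == best


def test_opposite_quartets_tie_break_deterministically():
    g1 = _t.read_newick("((A,B),(C,D));")
    g2 = _t.read_newick("((A,C),(B,D));")
    c1 = consensus_species_tree([g1, g2])
    c2 = consensus_species_tree([g2, g1])
    assert _t.canonical_topology(c1) == _t.canonical_topology(c2)
    # the canonical smallest newick among tied optima starts with A paired
    assert robinson_foulds(c1, c2)[0] == 0


def test_consensus_requires_two_trees_and_four_taxa():
    g1 = _t.read_newick("((A,B),(C,D));")
    with pytest.raises(SpeciesTreeError):
        consensus_species_tree([g1])
    tri = _t.read_newick("(A,B,C);")
    with pytest.raises(SpeciesTreeError):
        consensus_species_tree([tri, tri])


def test_heuristic_mode_recovers_clear_signal_above_exact_limit():
    rnd = random.Random(9)
    labels = [f"t{i}" for i in range(9)]
    topo = _t.random_binary_tree(labels, rnd)
    gts = [_t.read_newick(_t.to_newick(topo)) for _ in range(6)]
    cons = consensus_species_tree(gts, taxa_limit_exact=6)
    assert robinson_foulds(topo, cons)[0] == 0


# ---------------------------------------------------------------------------
# supermatrix tree + bootstrap
# ---------------------------------------------------------------------------

def _signal_supermatrix(reps=30):
    """Every column carries the split ab|cd."""
    rows = [
        ("a", "AACC" * reps),
        ("b", "AACC" * reps),
        ("c", "CCAA" * reps),
        ("d", "CCAA" * reps),
    ]
    m = Msa(rows, Alphabet.NUCLEOTIDE4)
    return concatenate({"m1": m})


def test_supermatrix_tree_column_order_invariance(rng):
    from phylomark.simulate import (
        evolve_sequences,
        random_sequence,
        simulate_yule_tree,
    )

    tree = simulate_yule_tree(6, seed=3)
    msas = {}
    for i in range(3):
        root = random_sequence(200, rng)
        leaves = evolve_sequences(tree, root, 0.1, seed=50 + i)
        msas[f"m{i}"] = Msa(sorted(leaves.items()), Alphabet.AMINO20)
    t1 = supermatrix_tree(concatenate(msas))
    # permuting marker order cannot change distances
    t2 = supermatrix_tree(
        concatenate({"zz_m0": msas["m0"], "a_m1": msas["m1"], "m2": msas["m2"]})
    )
    assert robinson_foulds(t1, t2)[0] == 0
    assert robinson_foulds(t1, tree)[0] == 0  # simulate-then-recover


def test_supermatrix_all_gap_overlap_is_reported():
    m = Msa(
        [("a", "AC--"), ("b", "--AC"), ("c", "ACAC"), ("d", "ACAC")],
        Alphabet.NUCLEOTIDE4,
    )
    sm = concatenate({"m1": m})
    with pytest.raises(Exception, match="share no"):
        supermatrix_tree(sm)


def test_bootstrap_constant_signal_gives_full_support():
    sm = _signal_supermatrix()
    tree = supermatrix_tree(sm)
    st = bootstrap_support(sm, tree, replicates=50, seed=3)
    assert set(st.bootstrap.values()) == {100.0}


def test_bootstrap_is_seed_reproducible_and_bounded(study_pipeline):
    from phylomark import read_fasta_msa

    sm = concatenate(
        {
            mid: read_fasta_msa(p, Alphabet.AMINO20)
            for mid, p in list(study_pipeline["align"]["alignments"].items())[:5]
        }
    )
    tree = supermatrix_tree(sm)
    s1 = bootstrap_support(sm, tree, replicates=30, seed=11)
    s2 = bootstrap_support(sm, tree, replicates=30, seed=11)
    assert s1.bootstrap == s2.bootstrap
    assert all(0.0 <= v <= 100.0 for v in s1.bootstrap.values())


# ---------------------------------------------------------------------------
# concordance factors
# ---------------------------------------------------------------------------

def test_gcf_extremes():
    sp = _t.read_newick("((A,B),(C,D),E);")
    agree = [_t.read_newick("((A,B),(C,D),E);") for _ in range(4)]
    gcf = gene_concordance(sp, agree)
    assert set(gcf.values()) == {100.0}
    disagree = [_t.read_newick("((A,C),(B,D),E);") for _ in range(4)]
    gcf0 = gene_concordance(sp, disagree)
    ab_split = frozenset({"C", "D"})  # side not containing min label A
    # the AB|CDE branch is present in neither discordant tree
    assert 0.0 in gcf0.values()


def test_scf_near_100_with_zero_discordance(study_pipeline):
    st = study_pipeline["concat"]["supported"]
    values = [v for v in st.scf.values() if v is not None]
    assert values
    assert all(v >= 95.0 for v in values)


def test_supported_newick_round_trip(study_pipeline):
    st = study_pipeline["concat"]["supported"]
    text = write_supported_newick(st)
    back = read_supported_newick(text)
    assert robinson_foulds(st.tree, back.tree)[0] == 0
    for split, val in st.bootstrap.items():
        assert back.bootstrap[split] == pytest.approx(val, abs=1e-9)
    for split, val in st.gcf.items():
        assert back.gcf[split] == pytest.approx(val, abs=1e-9)
    for split, val in st.scf.items():
        if val is None:
            assert split not in (back.scf or {})
        else:
            assert back.scf[split] == pytest.approx(val, abs=1e-9)
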