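"""JC distances, neighbor-joining, Robinson–Foulds, acceleration screen."""

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from sbgturnover.io_formats import read_newick, write_newick
from sbgturnover.phylo import (
    bipartitions,
    jc_distance,
    jc_distance_matrix,
    nj_tree,
    rf_distance,
    terminal_branch_screen,
)
from sbgturnover.synth import simulate_alignment


# ------------------------------------------------------------ JC distances


def test_jc_identical_sequences_have_zero_distance():
    dm = jc_distance_matrix({"A": "ACGTACGT", "B": "ACGTACGT"})
    assert dm.loc["A", "B"] == 0.0


def test_jc_closed_form_at_p_030():
    assert jc_distance(0.3) == pytest.approx(-0.75 * math.log(0.6))
    assert jc_distance(0.3) == pytest.approx(0.3831, abs=5e-4)


def test_jc_monotone_in_mismatch_fraction():
    ps = np.linspace(0, 0.74, 50)
    ds = [jc_distance(p) for p in ps]
    assert all(b > a for a, b in zip(ds, ds[1:]))


def test_jc_unequal_lengths_rejected():
    with pytest.raises(ValueError, match="unequal"):
        jc_distance_matrix({"A": "ACGT", "B": "ACG"})


def test_jc_saturation_error_and_cap():
    aln = {"A": "AAAA", "B": "CCCC"}
    with pytest.raises(ValueError, match="saturated"):
        jc_distance_matrix(aln)
    dm = jc_distance_matrix(aln, on_saturation="cap", saturation_cap=5.0)
    assert dm.loc["A", "B"] == 5.0


def test_jc_matrix_consistent_with_path_lengths(rng):
    tree = read_newick("((A:0.05,B:0.08):0.04,(C:0.06,D:0.1):0.03);")
    L = 100_000
    aln = simulate_alignment(tree, L, rng)
    dm = jc_distance_matrix(aln)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for a, b in itertools.combinations("ABCD", 2):
        true_d = pdm.patristic_distance(taxa[a], taxa[b])
        q = 0.75 * (1 - math.exp(-4 * true_d / 3))
        se_p = math.sqrt(q * (1 - q) / L)
        # delta method: SE(d) = SE(p) / (1 - 4p/3)
        se_d = se_p / (1 - 4 * q / 3)
        assert abs(dm.loc[a, b] - true_d) < 3 * se_d


# -------------------------------------------------------- neighbor-joining


def _additive_matrix():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise path lengths
    return pd.DataFrame(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        index=list("ABCD"), columns=list("ABCD"), dtype=float,
    )


def test_nj_exact_on_additive_four_taxon_matrix():
    tree = nj_tree(_additive_matrix())
    truth = read_newick("((A:1,B:2):1,(C:3,D:4):0);")
    assert rf_distance(tree, truth).rf == 0
    term = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert term == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
    # four-point condition: the split AB|CD dominates
    d = _additive_matrix()
    assert d.loc["A", "B"] + d.loc["C", "D"] < d.loc["A", "C"] + d.loc["B", "D"]


def test_nj_three_taxa_closed_form():
    dm = pd.DataFrame(
        [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
        index=list("ABC"), columns=list("ABC"), dtype=float,
    )
    tree = nj_tree(dm)
    term = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert term["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert term["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert term["C"] == pytest.approx((4 + 5 - 3) / 2)


def test_nj_invariant_to_input_permutation():
    dm = _additive_matrix()
    perm = ["C", "A", "D", "B"]
    t1 = nj_tree(dm)
    t2 = nj_tree(dm.loc[perm, perm])
    assert rf_distance(t1, t2).rf == 0
    assert sum(e.length for e in t1.preorder_edge_iter() if e.length) == (
        pytest.approx(sum(e.length for e in t2.preorder_edge_iter() if e.length))
    )


def test_nj_rejects_bad_matrices():
    dm = _additive_matrix()
    bad = dm.copy()
    bad.iloc[0, 1] = -1
    bad.iloc[1, 0] = -1
    with pytest.raises(ValueError, match="negative"):
        nj_tree(bad)
    bad2 = dm.copy()
    bad2.iloc[0, 1] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        nj_tree(bad2)


def test_nj_recovers_planted_topologies(rng):
    """10 replicates, 8 taxa, 10,000 sites: RF to truth 0 in >= 9 of 10."""
    tree_text = (
        "(((A:0.05,B:0.07):0.04,(C:0.06,D:0.05):0.05):0.03,"
        "((E:0.08,F:0.04):0.05,(G:0.06,H:0.07):0.04):0.03);"
    )
    hits = 0
    for _ in range(10):
        truth = read_newick(tree_text)
        aln = simulate_alignment(truth, 10_000, rng)
        est = nj_tree(jc_distance_matrix(aln))
        hits += rf_distance(est, truth).rf == 0
    assert hits >= 9


def test_nj_matches_independent_implementation(rng):
    """Topology agrees with dendropy's own NJ on a random noisy matrix."""
    n = 7
    labels = [f"T{i}" for i in range(n)]
    base = rng.uniform(0.1, 1.0, size=(n, n))
    d = (base + base.T) / 2
    np.fill_diagonal(d, 0)
    dm = pd.DataFrame(d, index=labels, columns=labels)
    mine = nj_tree(dm)

    csv = "," + ",".join(labels) + "\n"
    for i, lab in enumerate(labels):
        csv += lab + "," + ",".join(f"{d[i, j]:.8f}" for j in range(n)) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=__import__("io").StringIO(csv), delimiter=","
    )
    their_tree = pdm.nj_tree()
    for e in their_tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            e.length = 0.0  # dendropy's NJ leaves raw negative estimates
    theirs = read_newick(their_tree.as_string(schema="newick").replace("'", ""))
    assert rf_distance(mine, theirs).rf == 0


# ---------------------------------------------------------- Robinson–Foulds


def test_rf_of_identical_trees_is_zero():
    t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    rep = rf_distance(t, read_newick("((A:1,B:1):1,(C:1,D:1):1);"))
    assert rep.rf == 0
    assert rep.normalized_rf == 0.0
    assert rep.discordant_splits == []


def test_rf_of_conflicting_quartets_is_two():
    a = read_newick("((A,B),(C,D));")
    b = read_newick("((A,C),(B,D));")
    rep = rf_distance(a, b)
    assert rep.rf == 2
    assert rep.max_rf == 2
    assert rep.normalized_rf == 1.0
    assert sorted(rep.discordant_splits) == [("B", "D"), ("C", "D")]


def test_rf_of_caterpillar_and_its_nni_neighbor():
    a = read_newick("(((( A , B ):1,C):1,D):1,E);".replace(" ", ""))
    b = read_newick("((((A,C):1,B):1,D):1,E);")
    assert rf_distance(a, b).rf == 2


def test_rf_requires_identical_leaf_sets():
    with pytest.raises(ValueError, match="only in first"):
        rf_distance(read_newick("((A,B),(C,D));"), read_newick("((A,B),(C,E));"))


def test_rf_is_a_metric_on_random_topologies(rng):
    taxa = dendropy.TaxonNamespace([f"T{i}" for i in range(8)])
    trees = [
        dendropy.simulate.treesim.birth_death_tree(
            1.0, 0.0, taxon_namespace=taxa, num_extant_tips=8,
            rng=__import__("random").Random(int(rng.integers(2**31))),
        )
        for _ in range(3)
    ]
    trees = [read_newick(t.as_string(schema="newick").replace("'", "")) for t in trees]
    d = {}
    for i, j in itertools.combinations(range(3), 2):
        rep = rf_distance(trees[i], trees[j])
        d[(i, j)] = d[(j, i)] = rep.rf
        assert rep.rf % 2 == 0
        assert rep.rf == rf_distance(trees[j], trees[i]).rf
    for i in range(3):
        assert rf_distance(trees[i], trees[i]).rf == 0
    assert d[(0, 2)] <= d[(0, 1)] + d[(1, 2)]


def test_bipartitions_ignore_rooting():
    rooted = read_newick("(((A,B),C),(D,E));")
    rerooted = read_newick("((D,E),((A,B),C));")
    assert bipartitions(rooted) == bipartitions(rerooted)


# ------------------------------------------------- terminal-branch screen


def test_equal_terminals_are_never_flagged():
    t = read_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
    rep = terminal_branch_screen(t)
    assert rep.flagged == []
    assert all(r.ratio == pytest.approx(1.0) for r in rep.rows)


def test_ten_fold_terminal_is_flagged_at_defaults():
    t = read_newick(
        "(((A:1.0,B:0.1):0.05,(C:0.1,D:0.1):0.05):0.02,"
        "((E:0.1,F:0.1):0.05,(G:0.1,H:0.1):0.05):0.02);"
    )
    rep = terminal_branch_screen(t)
    assert rep.flagged == ["A"]
    assert rep.rows[0].leaf == "A"  # sorted by ratio, largest first
    assert rep.rows[0].ratio == pytest.approx(10.0)


def test_screen_rejects_degenerate_trees():
    with pytest.raises(ValueError, match="4 leaves"):
        terminal_branch_screen(read_newick("((A:1,B:1):1,C:1);"))
    with pytest.raises(ValueError, match="median"):
        terminal_branch_screen(read_newick("((A:0,B:0):1,(C:0,D:0):1);"))


def test_newick_round_trip_of_nj_output():
    tree = nj_tree(_additive_matrix())
    again = read_newick(write_newick(tree))
    assert rf_distance(tree, again).rf == 0
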