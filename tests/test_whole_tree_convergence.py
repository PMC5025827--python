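import itertools
from fractions import Fraction

import numpy as np
import pytest

from convergia.matrix_io import CharacterMatrix, RootedTree
from convergia.parsimony_core import MPRSummary
from convergia.whole_tree_convergence import (
    BranchPair,
    PairEventCounts,
    analyze_whole_tree,
    enumerate_independent_pairs,
    pair_event_weights,
    pair_fisher_tests,
    round_half_up,
    state_binned_ratio,
)

from conftest import brute_force_mprs, make_column, random_column, random_rooted_tree

TAXA4 = ["Y1", "Y2", "Y3", "Y4"]


def brute_force_pairs(tree):
    """Oracle: check the three independence conditions edge-pair by pair."""
    edges = tree.edges()
    out = []
    for e1, e2 in itertools.combinations(edges, 2):
        nodes = {*e1, *e2}
        if len(nodes) != 4:
            continue
        path = lambda n: tree.ancestors(n) | {n}
        if e1[1] in path(e2[1]) or e2[1] in path(e1[1]):
            continue
        out.append(frozenset([e1, e2]))
    return set(out)


class TestEnumerateIndependentPairs:
    def test_quartet_tree_has_eight(self, quartet_tree):
        pairs = enumerate_independent_pairs(quartet_tree)
        assert len(pairs) == 8
        got = {
            frozenset([(p.parent1, p.child1), (p.parent2, p.child2)])
            for p in pairs
        }
        assert got == brute_force_pairs(quartet_tree)

    def test_three_leaf_tree_matches_oracle(self):
        tree = RootedTree.from_newick("(A,(B,C));")
        pairs = enumerate_independent_pairs(tree)
        got = {
            frozenset([(p.parent1, p.child1), (p.parent2, p.child2)])
            for p in pairs
        }
        assert got == brute_force_pairs(tree)

    def test_no_shared_nodes(self):
        rng = np.random.default_rng(2)
        tree = random_rooted_tree([f"t{i}" for i in range(7)], rng)
        for p in enumerate_independent_pairs(tree):
            assert len(set(p.nodes())) == 4

    def test_random_trees_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            tree = random_rooted_tree([f"t{i}" for i in range(6)], rng)
            got = {
                frozenset([(p.parent1, p.child1), (p.parent2, p.child2)])
                for p in enumerate_independent_pairs(tree)
            }
            assert got == brute_force_pairs(tree)


def oracle_pair_weights(column, tree, pair):
    """Oracle: average the convergence/divergence indicator over all MPRs."""
    _, mprs = brute_force_mprs(column, tree)
    cv = dv = 0
    for m in mprs:
        x1, x3 = m[pair.parent1], m[pair.child1]
        x2, x4 = m[pair.parent2], m[pair.child2]
        if x1 != x3 and x2 != x4:
            if x3 == x4:
                cv += 1
            else:
                dv += 1
    return Fraction(cv, len(mprs)), Fraction(dv, len(mprs))


def find_pair(tree, label_a, label_b):
    na, nb = tree.node_of(label_a), tree.node_of(label_b)
    for p in enumerate_independent_pairs(tree):
        if {p.child1, p.child2} == {na, nb}:
            return p
    raise AssertionError("pair not found")


class TestPairEventWeights:
    def test_abab_cross_pair_converges(self, quartet_tree, abab_column):
        s = MPRSummary(abab_column, quartet_tree)
        pair = find_pair(quartet_tree, "Y2", "Y4")
        assert pair_event_weights(s, pair) == (Fraction(1, 2), 0)

    def test_abab_y1y4_pair_is_silent(self, quartet_tree, abab_column):
        s = MPRSummary(abab_column, quartet_tree)
        pair = find_pair(quartet_tree, "Y1", "Y4")
        assert pair_event_weights(s, pair) == (0, 0)

    def test_abac_diverges(self, quartet_tree):
        col = make_column(TAXA4, ["A", "B", "A", "C"])
        s = MPRSummary(col, quartet_tree)
        pair = find_pair(quartet_tree, "Y2", "Y4")
        assert pair_event_weights(s, pair) == (0, Fraction(1))

    def test_cv_plus_dv_at_most_one(self):
        rng = np.random.default_rng(21)
        tree = random_rooted_tree([f"t{i}" for i in range(6)], rng)
        col = random_column([f"t{i}" for i in range(6)], rng, p_missing=0.2)
        s = MPRSummary(col, tree)
        for pair in enumerate_independent_pairs(tree):
            cv, dv = pair_event_weights(s, pair)
            assert 0 <= cv + dv <= 1

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_mpr_enumeration(self, trial):
        rng = np.random.default_rng(3000 + trial)
        taxa = [f"t{i}" for i in range(6)]
        tree = random_rooted_tree(taxa, rng)
        col = random_column(taxa, rng, max_states=3, p_missing=0.1)
        s = MPRSummary(col, tree)
        pairs = enumerate_independent_pairs(tree)
        for pair in pairs:
            assert pair_event_weights(s, pair) == oracle_pair_weights(col, tree, pair)

    def test_unique_mpr_gives_integer_weights(self, quartet_tree):
        col = make_column(TAXA4, ["A", "B", "A", "C"])
        s = MPRSummary(col, quartet_tree)
        assert s.mpr_count == 1
        for pair in enumerate_independent_pairs(quartet_tree):
            cv, dv = pair_event_weights(s, pair)
            assert cv in (0, 1) and dv in (0, 1)


class TestPairFisherTests:
    def test_paper_style_tables(self):
        counts = PairEventCounts(
            cv={"morphological": 24.67, "molecular": 21.88},
            dv={"morphological": 9.84, "molecular": 88.57},
            n_chars={"morphological": 3414, "molecular": 5722},
        )
        res = pair_fisher_tests(counts)
        assert res.defined
        assert res.p_conv == pytest.approx(0.0332, abs=5e-5)
        assert res.p_cvdv == pytest.approx(3.9e-8, rel=0.05)

    def test_undefined_pair_flagged(self):
        counts = PairEventCounts(
            cv={"morphological": 2.0, "molecular": 0.0},
            dv={"morphological": 1.0, "molecular": 0.4},
            n_chars={"morphological": 10, "molecular": 10},
        )
        res = pair_fisher_tests(counts)
        assert not res.defined and res.p_conv is None

    def test_round_half_up(self):
        assert round_half_up(24.67) == 25
        assert round_half_up(21.88) == 22
        assert round_half_up(9.84) == 10
        assert round_half_up(88.57) == 89
        assert round_half_up(2.5) == 3


class TestStateBinnedRatio:
    def test_single_bin(self):
        r = state_binned_ratio(
            [0.2, 0.2, 0.4, 0.4],
            [2, 2, 2, 2],
            ["morphological", "morphological", "molecular", "molecular"],
        )
        assert r == pytest.approx(0.5)

    def test_weighted_two_bins(self):
        ratios = [1.0, 1.0, 1.0, 1.0, 0.5, 1.0]
        states = [2, 2, 2, 2, 3, 3]
        types = ["morphological"] * 3 + ["molecular"] + ["morphological", "molecular"]
        # bin 2: morph mean 1.0 / mol mean 1.0 = 1.0, weight 3
        # bin 3: morph mean 0.5 / mol mean 1.0 = 0.5, weight 1
        r = state_binned_ratio(ratios, states, types)
        assert r == pytest.approx((3 * 1.0 + 1 * 0.5) / 4)

    def test_identity(self):
        r = state_binned_ratio(
            [1.0, 1.0, 1.0, 1.0],
            [2, 2, 3, 3],
            ["morphological", "molecular", "morphological", "molecular"],
        )
        assert r == pytest.approx(1.0)

    def test_lonely_bin_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            r = state_binned_ratio(
                [1.0, 2.0, 1.0],
                [2, 2, 5],
                ["morphological", "molecular", "morphological"],
            )
        assert r == pytest.approx(0.5)

    def test_undefined_ratios_excluded(self):
        r = state_binned_ratio(
            [0.2, float("nan"), 0.4, float("inf")],
            [2, 2, 2, 2],
            ["morphological", "morphological", "molecular", "molecular"],
        )
        assert r == pytest.approx(0.5)


class TestAnalyzeWholeTree:
    def test_small_end_to_end(self, quartet_tree):
        cols = [
            make_column(TAXA4, ["A", "B", "A", "B"], col_id="m1"),
            make_column(TAXA4, ["A", "A", "B", "B"], col_id="m2"),
            make_column(TAXA4, ["C", "D", "C", "D"], col_id="s1",
                        type_tag="molecular"),
        ]
        matrix = CharacterMatrix(TAXA4, cols)
        pair_table, char_table = analyze_whole_tree(matrix, quartet_tree)
        assert len(pair_table) == 8
        assert set(char_table["id"]) == {"m1", "m2", "s1"}
        m1 = char_table.set_index("id").loc["m1"]
        # ABAB: pairs (Y1,Y3) and (Y2,Y4) each gain 1/2 convergence
        assert m1["cv"] == pytest.approx(1.0)
        m2 = char_table.set_index("id").loc["m2"]
        assert m2["cv"] == pytest.approx(0.0)
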