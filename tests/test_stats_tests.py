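import itertools

import numpy as np
import pytest
from scipy import stats as sps

from convergia.matrix_io import CharacterMatrix
from convergia.stats_tests import (
    bh_qvalues,
    bootstrap_majority_test,
    fisher_exact_2x2,
    mann_whitney,
    partial_correlation,
    resample_characters,
)

from conftest import make_column


class TestFisherExact:
    def test_first_reference_table(self):
        # worked example: convergent vs non-convergent characters
        assert fisher_exact_2x2(25, 3389, 22, 5700) == pytest.approx(0.0332, abs=5e-5)

    def test_second_reference_table(self):
        assert fisher_exact_2x2(25, 10, 22, 89) == pytest.approx(3.9e-8, rel=0.05)

    def test_balanced_table(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == 1.0

    def test_identical_rows(self):
        assert fisher_exact_2x2(10, 90, 10, 90) == 1.0

    def test_negative_cell_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2(0, 0, 3, 4) == 1.0

    def test_symmetry_under_row_and_column_swap(self):
        for a, b, c, d in [(3, 7, 9, 2), (1, 5, 5, 1), (12, 3, 4, 8)]:
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_exact_2x2(d, c, b, a)
            )


class TestBHQvalues:
    def test_hand_example(self):
        assert bh_qvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_qvalues([0.37]) == [0.37]

    def test_all_ones(self):
        assert bh_qvalues([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_empty(self):
        assert bh_qvalues([]) == []

    def test_monotone_in_pvalues(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.random(20))
        q = bh_qvalues(list(p))
        p2 = p.copy()
        p2[10] = min(p2[10] * 1.5, 1.0)
        q2 = bh_qvalues(list(p2))
        assert q2[10] >= q[10] - 1e-12


class TestBootstrapMajorityTest:
    @staticmethod
    def _analysis(matrix: CharacterMatrix):
        # one 'unit' per taxon: mean state value per type as a toy statistic
        morph = matrix.columns_of_type("morphological")
        mol = matrix.columns_of_type("molecular")
        out = []
        for t in matrix.taxa:
            mval = np.mean([int(next(iter(c.entries[t]))) for c in morph])
            oval = np.mean([int(next(iter(c.entries[t]))) for c in mol])
            out.append((mval, oval))
        return out

    def _matrix(self, morph_states, mol_states):
        taxa = ["t1", "t2", "t3", "t4"]
        cols = [
            make_column(taxa, s, col_id=f"m{i}")
            for i, s in enumerate(morph_states)
        ] + [
            make_column(taxa, s, col_id=f"s{i}", type_tag="molecular")
            for i, s in enumerate(mol_states)
        ]
        return CharacterMatrix(taxa, cols)

    def test_extreme_difference_gives_zero(self):
        m = self._matrix([["1", "1", "1", "0"]] * 5, [["0", "0", "0", "1"]] * 5)
        res = bootstrap_majority_test(m, self._analysis, B=50, seed=1)
        assert res.p_value == 0.0

    def test_exchangeable_types_symmetric_on_average(self):
        # P for one fixed dataset concentrates on whichever side that
        # dataset favors; under identically drawn types, swapping the two
        # type labels must leave the distribution of P unchanged.
        rng = np.random.default_rng(4)
        ps, ps_swapped = [], []
        for rep in range(12):
            states = [
                [str(rng.integers(2)) for _ in range(4)] for _ in range(20)
            ]
            m = self._matrix(states[:10], states[10:])
            m_swap = self._matrix(states[10:], states[:10])
            ps.append(
                bootstrap_majority_test(m, self._analysis, B=40, seed=rep).p_value
            )
            ps_swapped.append(
                bootstrap_majority_test(
                    m_swap, self._analysis, B=40, seed=rep
                ).p_value
            )
        assert abs(np.mean(ps) - np.mean(ps_swapped)) < 0.2

    def test_single_replicate_is_binary(self):
        m = self._matrix([["1", "1", "0", "0"]], [["0", "1", "0", "1"]])
        res = bootstrap_majority_test(m, self._analysis, B=1, seed=3)
        assert res.p_value in (0.0, 1.0)

    def test_invalid_b_errors(self):
        m = self._matrix([["1", "0", "1", "0"]], [["0", "1", "0", "1"]])
        with pytest.raises(ValueError):
            bootstrap_majority_test(m, self._analysis, B=0)

    def test_seed_reproducible(self):
        m = self._matrix([["1", "1", "0", "0"]] * 3, [["0", "1", "0", "1"]] * 3)
        r1 = bootstrap_majority_test(m, self._analysis, B=25, seed=11)
        r2 = bootstrap_majority_test(m, self._analysis, B=25, seed=11)
        assert r1.p_value == r2.p_value

    def test_resample_preserves_type_counts(self):
        m = self._matrix([["1", "0", "1", "0"]] * 4, [["0", "1", "0", "1"]] * 7)
        rng = np.random.default_rng(0)
        s = resample_characters(m, rng)
        assert len(s.columns_of_type("morphological")) == 4
        assert len(s.columns_of_type("molecular")) == 7


class TestMannWhitney:
    def test_identical_paired_samples(self):
        with pytest.warns(UserWarning):
            assert mann_whitney([1, 2, 3], [1, 2, 3], paired=True) == 1.0

    def test_shifted_distributions_significant(self):
        rng = np.random.default_rng(8)
        x = rng.normal(2.0, 1.0, 50)
        y = rng.normal(0.0, 1.0, 50)
        assert mann_whitney(x, y) < 0.01
        assert mann_whitney(x, y, paired=True) < 0.01

    def test_small_vectors_match_exact_enumeration(self):
        x = [1.0, 3.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0]
        # brute-force two-sided exact p from the U null distribution
        pooled = x + y
        obs_u = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
            1 for xi in x for yi in y if xi == yi
        )
        us = []
        for comb in itertools.combinations(range(7), 3):
            xs = [pooled[i] for i in comb]
            ys = [pooled[i] for i in range(7) if i not in comb]
            us.append(
                sum(1 for xi in xs for yi in ys if xi > yi)
                + 0.5 * sum(1 for xi in xs for yi in ys if xi == yi)
            )
        mu = len(x) * len(y) / 2
        exact = sum(1 for u in us if abs(u - mu) >= abs(obs_u - mu) - 1e-9) / len(us)
        assert mann_whitney(x, y) == pytest.approx(exact)

    def test_paired_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([1, 2], [1, 2, 3], paired=True)


class TestPartialCorrelation:
    def test_independent_control_equals_pearson(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=500)
        y = x + rng.normal(size=500)
        z = rng.normal(size=500)
        r_partial = partial_correlation(x, y, z)
        r_plain = np.corrcoef(x, y)[0, 1]
        assert r_partial == pytest.approx(r_plain, abs=0.05)

    def test_degenerate_control_flagged(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 4.0, 6.0, 8.0]
        with pytest.warns(UserWarning):
            assert np.isnan(partial_correlation(x, y, y))

    def test_matches_residual_regression(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 7.0, 5.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 6.0, 8.0])
        z = np.array([0.5, 1.5, 2.0, 3.5, 5.0, 4.0])
        def residuals(v, w):
            slope, intercept, *_ = sps.linregress(w, v)
            return v - (slope * w + intercept)
        expected = np.corrcoef(residuals(x, z), residuals(y, z))[0, 1]
        assert partial_correlation(x, y, z) == pytest.approx(expected)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(partial_correlation([1, 1, 1, 1], [1, 2, 3, 4],
                                                [4, 3, 2, 1]))
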