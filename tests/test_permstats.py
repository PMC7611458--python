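"""Exact permutation tests, effect sizes and corrections."""

from itertools import combinations, product
from math import comb

import numpy as np
import pytest

from mrsquant.permstats import (
    DegenerateDataError,
    bidirectional_correction,
    bonferroni_threshold,
    chi_square_yates,
    cohens_d,
    fwer_correct_batch,
    pearson_with_p,
    permutation_two_sample,
    sign_flip_test,
)

RNG = np.random.default_rng(1234)


class TestSignFlip:
    def test_n11_enumerates_2048_shufflings(self):
        res = sign_flip_test(RNG.normal(1, 1, 11))
        assert res.n_shufflings == 2048
        assert res.exhaustive

    def test_n4_all_positive_smallest_p(self):
        res = sign_flip_test(np.array([0.3, 0.5, 0.9, 1.4]))
        assert res.n_shufflings == 16
        assert res.p_uncorrected_onetailed == pytest.approx(1 / 16)

    def test_antisymmetric_data_two_tailed_p_is_one(self):
        res = sign_flip_test(np.array([-0.7, 0.7, -1.3, 1.3]))
        assert res.statistic == 0.0
        assert res.p_twotailed == 1.0

    def test_p_values_are_exact_multiples_of_reciprocal_count(self):
        for seed in range(5):
            d = np.random.default_rng(seed).normal(0.4, 1, 7)
            res = sign_flip_test(d)
            for p in (res.p_uncorrected_onetailed, res.p_twotailed):
                assert p >= 1 / res.n_shufflings - 1e-12
                assert np.isclose(p * res.n_shufflings, round(p * res.n_shufflings))

    def test_super_uniformity_under_symmetric_null(self):
        # full enumeration at n=6: for every attainable alpha,
        # P(p <= alpha) <= alpha over the 64 equally likely sign-flipped
        # versions of the data
        d = RNG.normal(0, 1, 6)
        ps = []
        for signs in product([-1.0, 1.0], repeat=6):
            ps.append(
                sign_flip_test(np.array(signs) * d).p_uncorrected_onetailed
            )
        ps = np.array(ps)
        for alpha in np.unique(ps):
            assert np.mean(ps <= alpha) <= alpha + 1e-12

    def test_monte_carlo_fallback_is_seeded(self):
        d = RNG.normal(0.5, 1, 25)
        a = sign_flip_test(d, max_exhaustive=1000, seed=7)
        b = sign_flip_test(d, max_exhaustive=1000, seed=7)
        assert not a.exhaustive and a.n_shufflings == 1000
        assert a.p_uncorrected_onetailed == b.p_uncorrected_onetailed

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            sign_flip_test(np.zeros(5))
        with pytest.raises(DegenerateDataError):
            sign_flip_test(np.array([1.0]))


class TestTwoSample:
    def test_study_group_sizes_give_1365_shufflings(self):
        res = permutation_two_sample(RNG.normal(1, 1, 11), RNG.normal(0, 1, 4))
        assert res.n_shufflings == comb(15, 4) == 1365
        assert res.exhaustive

    def test_brute_force_enumeration_oracle(self):
        # independent in-test enumeration of all C(6,3) assignments
        x = np.array([3.1, 2.7, 3.6])
        y = np.array([1.1, 0.8, 1.4])
        res = permutation_two_sample(x, y)
        pooled = np.concatenate([x, y])

        def tstat(a, b):
            sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
            return (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))

        stats = []
        for idx in combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(idx)] = True
            stats.append(tstat(pooled[mask], pooled[~mask]))
        t_obs = tstat(x, y)
        expected_one = np.mean(np.array(stats) >= t_obs - 1e-12)
        expected_two = np.mean(np.abs(stats) >= abs(t_obs) - 1e-12)
        assert res.p_uncorrected_onetailed == pytest.approx(expected_one)
        assert res.p_twotailed == pytest.approx(expected_two)
        # maximal separation: observed and its mirror are the extremes
        assert res.p_twotailed == pytest.approx(2 / comb(6, 3))

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            permutation_two_sample(np.ones(3), np.ones(3))


class TestCohensD:
    def test_t_d_identity_one_sample(self):
        x = RNG.normal(0.8, 1, 11)
        res = sign_flip_test(x)
        assert res.statistic == pytest.approx(res.cohens_d * np.sqrt(11), abs=1e-12)

    def test_t_d_identity_two_sample(self):
        x, y = RNG.normal(1, 1, 11), RNG.normal(0, 1, 4)
        res = permutation_two_sample(x, y)
        assert res.statistic == pytest.approx(
            res.cohens_d * np.sqrt(11 * 4 / 15), abs=1e-12
        )

    def test_scale_invariance(self):
        x = RNG.normal(2, 1, 9)
        assert cohens_d(x) == pytest.approx(cohens_d(5.0 * x), abs=1e-12)

    def test_zero_sd_undefined(self):
        with pytest.raises(DegenerateDataError):
            cohens_d(np.ones(4))


class TestFwerBatch:
    def test_singleton_family_unchanged(self):
        res = sign_flip_test(RNG.normal(1, 1, 8))
        (corrected,) = fwer_correct_batch([res])
        assert corrected == pytest.approx(res.p_twotailed)

    def test_perfectly_correlated_tests_unchanged(self):
        d = RNG.normal(0.9, 1, 8)
        r1 = sign_flip_test(d)
        r2 = sign_flip_test(2.0 * d)  # same t on every shuffling
        fwer_correct_batch([r1, r2])
        assert r1.p_fwer == pytest.approx(r1.p_twotailed)
        assert r2.p_fwer == pytest.approx(r2.p_twotailed)

    def test_independent_tests_corrected_upwards(self):
        r1 = sign_flip_test(RNG.normal(1.0, 1, 10))
        r2 = sign_flip_test(RNG.normal(0.1, 1, 10))
        fwer_correct_batch([r1, r2])
        assert r1.p_fwer >= r1.p_twotailed - 1e-12
        assert r2.p_fwer >= r2.p_twotailed - 1e-12

    def test_familywise_type_one_error_controlled(self):
        # 500 null simulations, family of two independent metabolites
        alpha = 0.05
        hits = 0
        rng = np.random.default_rng(99)
        for _ in range(500):
            r1 = sign_flip_test(rng.normal(0, 1, 8))
            r2 = sign_flip_test(rng.normal(0, 1, 8))
            fwer_correct_batch([r1, r2])
            hits += (r1.p_fwer <= alpha) or (r2.p_fwer <= alpha)
        # binomial 95% upper bound around alpha
        assert hits / 500 <= alpha + 1.96 * np.sqrt(alpha * (1 - alpha) / 500)

    def test_mismatched_schemes_rejected(self):
        r1 = sign_flip_test(RNG.normal(1, 1, 8))
        r2 = sign_flip_test(RNG.normal(1, 1, 9))
        with pytest.raises(ValueError, match="scheme"):
            fwer_correct_batch([r1, r2])

    def test_bonferroni_flag(self):
        r1 = sign_flip_test(RNG.normal(1, 1, 8))
        r2 = sign_flip_test(RNG.normal(1, 1, 8))
        fwer_correct_batch([r1, r2], method="bonferroni")
        assert r1.p_fwer == pytest.approx(min(1.0, 2 * r1.p_twotailed))


class TestBidirectional:
    def test_doubling_rule(self):
        assert bidirectional_correction(0.03, 0.98) == pytest.approx(0.06)

    def test_capped_at_one(self):
        assert bidirectional_correction(0.6, 0.6) == 1.0

    def test_equals_two_tailed_for_symmetric_enumeration(self):
        d = RNG.normal(0.6, 1, 9)
        res = sign_flip_test(d, tail="greater")
        assert res.p_bidirectional == pytest.approx(res.p_twotailed)


class TestBonferroniThreshold:
    def test_study_family_of_24(self):
        thr = bonferroni_threshold(0.05, 24)
        assert thr == pytest.approx(0.05 / 24)
        assert round(thr, 4) == 0.0021

    @pytest.mark.parametrize("m,expected", [(1, 0.05), (2, 0.025)])
    def test_simple_cases(self, m, expected):
        assert bonferroni_threshold(0.05, m) == expected

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestPearson:
    def test_collinear(self):
        res = pearson_with_p(np.arange(5.0), 2 * np.arange(5.0) + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_twotailed == 0.0

    def test_r055_n15_p_from_t_distribution(self):
        # t-distribution CDF oracle at the study's pooled correlation
        from scipy import stats as ss

        r, n = 0.55, 15
        t = r * np.sqrt((n - 2) / (1 - r**2))
        expected = 2 * ss.t.sf(t, n - 2)
        assert expected == pytest.approx(0.0335, abs=5e-4)
        # implementation agrees on data engineered to that r
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(size=n)
            y = 0.55 * x + rng.normal(size=n)
            res = pearson_with_p(x, y)
            assert res.p_twotailed == pytest.approx(
                2 * ss.t.sf(abs(res.t_statistic), 13), rel=1e-6
            )
            assert res.r_squared == pytest.approx(res.r**2, abs=1e-12)

    def test_antisymmetry(self):
        x = RNG.normal(size=8)
        assert pearson_with_p(x, -x).r == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_with_p(np.ones(5), np.arange(5.0))


class TestChiSquareYates:
    @staticmethod
    def yates_by_hand(tab):
        tab = np.asarray(tab, float)
        n = tab.sum()
        row, col = tab.sum(1), tab.sum(0)
        stat = 0.0
        for i in range(2):
            for j in range(2):
                e = row[i] * col[j] / n
                stat += (abs(tab[i, j] - e) - 0.5) ** 2 / e
        return stat

    def test_perfect_homogeneity(self):
        stat, p = chi_square_yates(np.array([[5, 5], [5, 5]]))
        assert stat == 0.0
        assert p == 1.0

    def test_ethnicity_table_matches_hand_formula(self):
        tab = np.array([[10, 1], [0, 4]])  # Caucasian vs not x MS vs NMOSD
        stat, p = chi_square_yates(tab)
        assert stat == pytest.approx(self.yates_by_hand(tab), rel=1e-12)
        assert 0 < p < 0.05

    def test_doubling_cells_increases_statistic(self):
        tab = np.array([[8, 2], [3, 7]])
        s1, _ = chi_square_yates(tab)
        s2, _ = chi_square_yates(2 * tab)
        assert s2 > s1

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateDataError):
            chi_square_yates(np.array([[0, 0], [5, 5]]))
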