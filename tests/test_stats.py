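"""Statistical machinery against independent oracles.

The repeated-measures ANOVA is checked against an explicit Hotelling-T2
matrix computation and against pingouin's one-sample multivariate t-test;
ordinal Krippendorff's alpha against a brute-force pair-enumeration oracle.
"""

import numpy as np
import pytest
from scipy import stats as sps

from respigate.stats import (
    bland_altman, bonferroni_pairwise, krippendorff_alpha_ordinal,
    one_sided_mean_test, relative_difference_percent, rm_anova_wilks,
)
from respigate.synthetic import gen_condition_table, gen_ordinal_ratings

from _oracles import hotelling_oracle, kripp_oracle_ordinal


class TestRmAnova:
    def test_identical_columns_no_effect(self):
        y = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = rm_anova_wilks(y)
        assert res.wilks_lambda == 1.0
        assert res.F == 0.0
        assert res.p == 1.0
        assert res.partial_eta_sq == 0.0

    def test_matches_matrix_oracle_on_toy_table(self, rng):
        y = rng.normal(0, 1, (5, 3)) + np.array([0.0, 0.5, 1.0])
        res = rm_anova_wilks(y)
        lam, f, p = hotelling_oracle(y)
        assert res.wilks_lambda == pytest.approx(lam, abs=1e-10)
        assert res.F == pytest.approx(f, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.df1 == 2 and res.df2 == 3

    def test_matches_pingouin_hotelling(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(0, 1, (12, 3)) + np.array([0.0, 0.3, 0.8])
        d = y[:, :-1] - y[:, 1:]
        ref = pingouin.multivariate_ttest(d)
        res = rm_anova_wilks(y)
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-9)

    def test_oracle_agreement_over_random_tables(self, rng):
        for _ in range(100):
            y = rng.normal(0, 1, (5, 3))
            res = rm_anova_wilks(y)
            lam, f, _ = hotelling_oracle(y)
            assert res.wilks_lambda == pytest.approx(lam, abs=1e-8)
            assert res.F == pytest.approx(f, abs=1e-8)
            assert res.partial_eta_sq == pytest.approx(1 - lam, abs=1e-12)

    def test_null_rejection_rate_calibrated(self):
        reps, hits = 400, 0
        for r in range(reps):
            table = gen_condition_table(12, (5.0, 5.0, 5.0), subject_sd=1.0,
                                        residual_sd=1.0, seed=20_000 + r)
            if rm_anova_wilks(table).p < 0.05:
                hits += 1
        assert 0.02 <= hits / reps <= 0.08

    def test_degenerate_metric_raises(self):
        y = np.tile(np.arange(5.0)[:, None], (1, 3))
        y[:, 1] += 1.0       # constant nonzero difference, zero variance
        with pytest.raises(ValueError, match="degenerate"):
            rm_anova_wilks(y)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            rm_anova_wilks(np.zeros((2, 3)))


class TestPairwise:
    def test_identical_columns_null_results(self):
        y = np.tile(np.arange(1.0, 6.0)[:, None], (1, 3))
        for res in bonferroni_pairwise(y):
            assert res.mean_diff == 0.0
            assert res.p_bonf == 1.0
            assert res.ci_low <= 0.0 <= res.ci_high

    def test_mirrored_pairs_antisymmetric(self):
        table = gen_condition_table(20, (10.0, 10.0, 8.2), seed=1)
        results = {r.pair: r for r in bonferroni_pairwise(table)}
        for (x, y), r in results.items():
            mirror = results[(y, x)]
            assert r.mean_diff == pytest.approx(-mirror.mean_diff)
            assert r.p_bonf == mirror.p_bonf
            assert r.ci_low == pytest.approx(-mirror.ci_high)

    def test_bonferroni_never_below_raw_p(self, rng):
        y = rng.normal(0, 1, (10, 3))
        cols = {"cam": 0, "nav": 1, "no": 2}
        for r in bonferroni_pairwise(y):
            a, b = cols[r.pair[0]], cols[r.pair[1]]
            raw = sps.ttest_rel(y[:, a], y[:, b]).pvalue
            assert r.p_bonf >= raw - 1e-15
            assert r.p_bonf <= 1.0

    def test_zero_variance_nonzero_diff(self):
        y = np.tile(np.arange(1.0, 6.0)[:, None], (1, 3))
        y[:, 2] -= 2.0
        results = {r.pair: r for r in bonferroni_pairwise(y)}
        r = results[("cam", "no")]
        assert r.mean_diff == pytest.approx(2.0)
        assert r.p_bonf == 0.0
        assert r.ci_low == r.ci_high == pytest.approx(2.0)

    def test_power_to_detect_ungated_difference(self):
        table = gen_condition_table(32, (10.0, 10.0, 8.2), subject_sd=1.0,
                                    residual_sd=1.0, seed=7)
        results = {r.pair: r for r in bonferroni_pairwise(table)}
        assert results[("cam", "no")].p_bonf < 0.01
        assert results[("nav", "no")].p_bonf < 0.01
        assert results[("cam", "nav")].p_bonf > 0.05


class TestKrippendorff:
    def test_perfect_agreement(self):
        ratings = gen_ordinal_ratings(30, 4, agreement="perfect", seed=0)
        assert krippendorff_alpha_ordinal(ratings).alpha == pytest.approx(1.0)

    def test_matches_brute_force_oracle_on_toy_tables(self, rng):
        for seed in range(10):
            g = np.random.default_rng(seed)
            values = g.integers(1, 5, size=(6, 3)).astype(float)
            # knock out a few entries to exercise the pairable-values rule
            mask = g.random((6, 3)) < 0.2
            values[mask] = np.nan
            if np.all(np.sum(~np.isnan(values), axis=1) < 2):
                continue
            ours = krippendorff_alpha_ordinal(values).alpha
            oracle = kripp_oracle_ordinal(values)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_chance_level_near_zero(self):
        ratings = gen_ordinal_ratings(500, 3, agreement="random", seed=3)
        assert abs(krippendorff_alpha_ordinal(ratings).alpha) <= 0.05

    def test_order_preserving_relabel_invariance(self):
        ratings = gen_ordinal_ratings(50, 3, agreement="high", seed=4)
        relabeled = ratings.replace({1: 10, 2: 20, 3: 30, 4: 40})
        assert krippendorff_alpha_ordinal(relabeled).alpha == pytest.approx(
            krippendorff_alpha_ordinal(ratings).alpha, abs=1e-12)

    def test_rater_permutation_invariance(self):
        ratings = gen_ordinal_ratings(50, 4, agreement="high", seed=5)
        shuffled = ratings[list(ratings.columns[::-1])]
        assert krippendorff_alpha_ordinal(shuffled).alpha == pytest.approx(
            krippendorff_alpha_ordinal(ratings).alpha, abs=1e-12)

    def test_unpairable_table_rejected(self):
        values = np.array([[1.0, np.nan], [np.nan, 2.0]])
        with pytest.raises(ValueError, match="pairable"):
            krippendorff_alpha_ordinal(values)


class TestBlandAltman:
    def test_identical_measurements(self):
        x = np.arange(10.0)
        res = bland_altman(x, x)
        assert res.bias == res.loa_low == res.loa_high == 0.0

    def test_constant_offset(self):
        x = np.arange(10.0)
        res = bland_altman(x, x - 2.0)
        assert res.bias == pytest.approx(2.0)
        assert res.sd_diff == 0.0

    def test_simulated_differences_match_plug_in(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 10_000)
        y = x - rng.normal(1.0, 2.0, 10_000)
        res = bland_altman(x, y)
        assert res.bias == pytest.approx(1.0, abs=0.07)
        assert res.loa_high == pytest.approx(1.0 + 1.96 * 2.0, abs=0.15)
        assert res.loa_low == pytest.approx(1.0 - 1.96 * 2.0, abs=0.15)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman(np.arange(3.0), np.arange(4.0))


class TestOneSidedTest:
    def test_values_at_threshold_give_half(self):
        assert one_sided_mean_test(np.full(5, 0.5), 0.5) == 0.5

    def test_strong_correlation_regime(self):
        rng = np.random.default_rng(2)
        values = np.clip(rng.normal(0.93, 0.09, 32), -1, 1)
        assert one_sided_mean_test(values, 0.5, "greater") < 0.01

    def test_direction_flip_complements(self, rng):
        values = rng.normal(0.7, 0.1, 20)
        p_gt = one_sided_mean_test(values, 0.5, "greater")
        p_lt = one_sided_mean_test(values, 0.5, "less")
        assert p_gt + p_lt == pytest.approx(1.0)


def test_relative_difference_rounds_to_expected_percent():
    value = relative_difference_percent(1.4, 15.8)
    assert round(value, 1) == 8.9
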