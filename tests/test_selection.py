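import numpy as np
import pytest
from scipy import stats

from dmdbold import (FeatureTable, LassoConfig, RepeatedLasso,
                     assemble_feature_table, call_abnormal_regions,
                     group_difference_permutation_test, lasso_fit,
                     mean_coefficients)


def _noise_table(n, p, seed, effect_col=None, effect_size=0.0):
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p))
    if effect_col is not None:
        X[labels == 1, effect_col] += effect_size
    return FeatureTable(values=X, feature_names=[f"f{j}" for j in range(p)],
                        labels=labels)


class TestLassoFit:
    def test_huge_gamma_shrinks_everything(self):
        table = _noise_table(40, 10, seed=0)
        beta = lasso_fit(table, LassoConfig(gamma=1e6, seed=0))
        assert np.all(beta == 0.0)

    def test_univariate_soft_threshold_oracle(self):
        """Single standardized feature: the fit must equal the closed-form
        soft threshold of the feature-label covariance at gamma/(2N)."""
        rng = np.random.default_rng(1)
        n = 60
        y = np.repeat([0, 1], n // 2).astype(float)
        for gamma in (0.2, 2.0, 20.0):
            x = 0.3 * y + rng.normal(size=n)
            x = (x - x.mean()) / x.std()
            cov = x @ (y - y.mean()) / n
            thr = gamma / (2 * n)
            expected = np.sign(cov) * max(abs(cov) - thr, 0.0)
            table = FeatureTable(values=x[:, None], feature_names=["f"],
                                 labels=y.astype(int))
            beta = lasso_fit(table, LassoConfig(gamma=gamma, seed=0))
            np.testing.assert_allclose(beta[0], expected, atol=1e-8)

    def test_planted_feature_selected_with_correct_sign(self):
        table = _noise_table(80, 50, seed=2, effect_col=7, effect_size=2.0)
        beta = lasso_fit(table, LassoConfig(gamma=0.2, seed=0))
        assert beta[7] > 0

    def test_constant_column_warns(self):
        table = _noise_table(40, 5, seed=3)
        table.values[:, 2] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            beta = lasso_fit(table, LassoConfig(seed=0))
        assert beta[2] == 0.0


class TestRepeatedSelection:
    def test_intersection_is_set_intersection(self):
        """The intersection equals the features nonzero in every run."""
        table = _noise_table(60, 30, seed=4, effect_col=3, effect_size=2.5)
        res = RepeatedLasso(table, LassoConfig(n_repeats=20, seed=4)).fit()
        expected = set(res.per_run_selected[0].tolist())
        for sel in res.per_run_selected[1:]:
            expected &= set(sel.tolist())
        assert set(res.intersection.tolist()) == expected
        assert 3 in expected

    def test_intersection_monotone_in_runs(self):
        table = _noise_table(60, 30, seed=5, effect_col=3, effect_size=2.0)
        sizes = []
        for n_repeats in (5, 20, 60):
            res = RepeatedLasso(table, LassoConfig(n_repeats=n_repeats,
                                                   seed=5)).fit()
            sizes.append(res.intersection.size)
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_selection_frequency_bounds(self):
        table = _noise_table(60, 30, seed=6, effect_col=3, effect_size=2.0)
        res = RepeatedLasso(table, LassoConfig(n_repeats=15, seed=6)).fit()
        freq = res.selection_frequency
        assert np.all((freq >= 0) & (freq <= 1))
        assert np.all(freq[res.intersection] == 1.0)

    def test_planted_recovery_small(self, small_planted_cohort):
        """Both planted (region, band) features survive the intersection and
        carry the planted coefficient signs."""
        cohort, effects = small_planted_cohort
        table = assemble_feature_table(cohort, mode="subband", k=3)
        res = RepeatedLasso(table, LassoConfig(n_repeats=50, seed=0)).fit()
        names = [table.feature_names[i] for i in res.intersection]
        coefs = dict(zip(names, res.mean_coefficients))
        assert "0.010-0.040Hz:ROI_005" in names
        assert "0.070-0.100Hz:ROI_017" in names
        assert coefs["0.010-0.040Hz:ROI_005"] > 0
        assert coefs["0.070-0.100Hz:ROI_017"] < 0

    def test_mean_coefficients(self):
        coefs = np.array([[0.2, 0.0], [0.4, 1.0]])
        np.testing.assert_allclose(
            mean_coefficients(coefs, np.array([0])), [0.3])
        same = np.tile([[0.5, -0.2]], (7, 1))
        np.testing.assert_allclose(
            mean_coefficients(same, np.array([0, 1])), [0.5, -0.2])


class TestPermutationTest:
    def test_constant_feature_p_is_one(self):
        labels = np.repeat([0, 1], 10)
        p = group_difference_permutation_test(np.ones(20), labels, B=100, seed=0)
        assert p == 1.0

    def test_perfect_separation_minimal_p(self):
        """Perfectly separated groups attain the smallest possible p: only
        the identity/complete-swap label arrangements (probability ~1e-5
        each among B random draws at n=15/group) reach the observed gap."""
        labels = np.repeat([0, 1], 15)
        x = labels.astype(float)
        p = group_difference_permutation_test(x, labels, B=1000, seed=0)
        assert p == pytest.approx(1 / 1001)

    def test_exhaustive_enumeration_tiny_n(self):
        """At n=3 per group the permutation null can be enumerated exactly:
        the add-one p-value must match the enumerated tail probability."""
        from itertools import combinations
        x = np.array([0.0, 0.1, 0.2, 1.0, 1.1, 1.2])
        labels = np.array([0, 0, 0, 1, 1, 1])
        observed = abs(x[labels == 1].mean() - x[labels == 0].mean())
        stats_all = []
        for ones in combinations(range(6), 3):
            perm = np.zeros(6, dtype=int)
            perm[list(ones)] = 1
            stats_all.append(abs(x[perm == 1].mean() - x[perm == 0].mean()))
        exact_tail = np.mean(np.asarray(stats_all) >= observed - 1e-12)
        B = 4000
        p = group_difference_permutation_test(x, labels, B=B, seed=1)
        # Monte-Carlo estimate of the enumerated tail (2/20 here)
        assert abs(p - exact_tail) < 0.02

    def test_p_value_bounds(self):
        rng = np.random.default_rng(7)
        labels = np.repeat([0, 1], 8)
        for seed in range(5):
            p = group_difference_permutation_test(
                rng.normal(size=16), labels, B=50, seed=seed)
            assert 1 / 51 <= p <= 1.0

    def test_null_p_values_uniform(self):
        """Permutation p-values on pure-noise features are approximately
        uniform (Kolmogorov-Smirnov distance < 0.1)."""
        rng = np.random.default_rng(8)
        labels = np.repeat([0, 1], 20)
        pvals = [
            group_difference_permutation_test(rng.normal(size=40), labels,
                                              B=200, seed=1000 + j)
            for j in range(300)
        ]
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1


class TestAbnormalCalls:
    def test_empty_intersection_empty_abnormal(self):
        table = _noise_table(40, 20, seed=9)
        res = RepeatedLasso(table, LassoConfig(n_repeats=30, seed=9)).fit()
        if res.intersection.size == 0:
            completed = call_abnormal_regions(res, table, B=50)
            assert completed.abnormal.size == 0

    def test_planted_effects_called_abnormal(self, small_planted_cohort):
        cohort, _ = small_planted_cohort
        table = assemble_feature_table(cohort, mode="subband", k=3)
        res = RepeatedLasso(table, LassoConfig(n_repeats=50, seed=0)).fit(
            permutation_B=200)
        abnormal = {table.feature_names[i] for i in res.abnormal}
        assert {"0.010-0.040Hz:ROI_005", "0.070-0.100Hz:ROI_017"} <= abnormal
        assert np.all(res.perm_pvalues >= 1 / 201)

    def test_type_I_error_on_prespecified_null_features(self):
        """The permutation test holds its nominal level on pure-noise
        features that were NOT chosen by looking at the data.  (Features
        that survive the LASSO intersection on the same cohort are selected
        *because* they correlate with the labels by chance, so their calls
        inherit that selection bias; the level guarantee applies to the
        test, not to the post-selection screen.)"""
        alpha = 0.05
        called, tested = 0, 0
        rng = np.random.default_rng(99)
        for seed in range(20):
            table = _noise_table(40, 30, seed=100 + seed)
            for j in range(table.n_features):
                p = group_difference_permutation_test(
                    table.values[:, j], table.labels, B=100,
                    seed=int(rng.integers(2**31)))
                tested += 1
                called += p < alpha
        se = np.sqrt(alpha * (1 - alpha) / tested)
        assert called / tested <= alpha + 3 * se

    def test_summary_table(self, small_planted_cohort):
        cohort, _ = small_planted_cohort
        table = assemble_feature_table(cohort, mode="subband", k=3)
        res = RepeatedLasso(table, LassoConfig(n_repeats=20, seed=1)).fit(
            permutation_B=50)
        frame = res.summary()
        assert {"feature", "mean_coefficient", "direction", "p_value",
                "abnormal"} <= set(frame.columns)
        assert len(frame) == res.intersection.size
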