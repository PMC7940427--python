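"""Unit and property tests for the shared statistical primitives."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scstage import statcore


class TestMadOutliers:
    def test_hand_computed_upper_flag(self):
        # median 3, MAD 1.4826 -> upper bound 3 + 3*1.4826 = 7.45
        flags = statcore.mad_outliers([1, 2, 3, 4, 100], k_upper=3)
        assert flags.tolist() == [False, False, False, False, True]

    def test_constant_vector_never_flags(self):
        flags = statcore.mad_outliers([5.0] * 10, k_lower=1, k_upper=1)
        assert not flags.any()

    def test_one_sided_rule_ignores_other_side(self):
        flags = statcore.mad_outliers([-1000, 1, 2, 3, 4], k_upper=3)
        assert not flags[0]  # no lower bound -> extreme low value passes

    def test_empty_and_all_nan_error(self):
        with pytest.raises(ValueError):
            statcore.mad_outliers([], k_upper=3)
        with pytest.raises(ValueError):
            statcore.mad_outliers([np.nan, np.nan], k_upper=3)

    @given(st.floats(0.1, 100), st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(7)
        v = rng.normal(size=40)
        v[0] = 25.0
        base = statcore.mad_outliers(v, k_lower=3, k_upper=3)
        trans = statcore.mad_outliers(scale * v + shift, k_lower=3, k_upper=3)
        assert (base == trans).all()

    def test_frozen_rule_reapplies_without_reestimation(self):
        v = np.array([1.0, 2, 3, 4, 100])
        rule = statcore.fit_mad_rule(v, k_lower=3, k_upper=3)
        kept = v[~rule.flags(v)]
        assert not statcore.mad_outliers(kept, rule=rule).any()


class TestHuberFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = statcore.huber_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)

    def test_resists_gross_outlier_better_than_ols(self):
        x = np.arange(20.0)
        y = x.copy()
        y[10] += 100.0
        fit = statcore.huber_fit(x, y)
        ols_slope = np.polyfit(x, y, 1)[0]
        assert abs(fit.slope - 1.0) < abs(ols_slope - 1.0)

    def test_iteration_cap_returns_unconverged(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.standard_cauchy(30)
        fit = statcore.huber_fit(x, y, max_it=1)
        assert fit.iterations <= 1
        assert not fit.converged

    def test_large_tuning_constant_matches_ols(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = 3 * x - 2 + rng.normal(size=50)
        fit = statcore.huber_fit(x, y, tuning_k=1e9)
        b1, b0 = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(b1, abs=1e-6)
        assert fit.intercept == pytest.approx(b0, abs=1e-6)

    def test_matches_statsmodels_rlm(self):
        """Independent cross-check against the RLM implementation."""
        import statsmodels.api as sm
        rng = np.random.default_rng(11)
        x = rng.normal(size=60)
        y = 1.5 * x + 0.5 + rng.normal(size=60)
        y[:5] += 8  # some outliers
        fit = statcore.huber_fit(x, y)
        rlm = sm.RLM(y, sm.add_constant(x),
                     M=sm.robust.norms.HuberT(t=1.345)).fit()
        assert fit.slope == pytest.approx(rlm.params[1], abs=5e-3)
        assert fit.intercept == pytest.approx(rlm.params[0], abs=5e-3)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            statcore.huber_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            statcore.huber_fit([1.0, 2.0], [1.0, 2.0])

    def test_weights_in_unit_interval(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        y = x + rng.standard_cauchy(40)
        fit = statcore.huber_fit(x, y)
        assert np.all(fit.weights >= 0) and np.all(fit.weights <= 1)


class TestRobustSlopeTest:
    def test_strong_trend_is_significant(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 1, 12)
        y = 5 * x + rng.normal(scale=0.2, size=12)
        fit = statcore.huber_fit(x, y)
        assert statcore.robust_slope_test(fit) < 1e-3

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        p1 = statcore.robust_slope_test(statcore.huber_fit(x, y))
        p2 = statcore.robust_slope_test(statcore.huber_fit(x, y))
        assert p1 == p2

    def test_null_calibration_small(self):
        """Type-I error near nominal at n=12 (reduced Monte-Carlo here;
        the full 1000-replicate calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(17)
        x = np.linspace(0, 1, 12)
        rej = sum(
            statcore.robust_slope_test(
                statcore.huber_fit(x, rng.normal(size=12))) < 0.05
            for _ in range(300))
        assert 0.02 <= rej / 300 <= 0.09


class TestBH:
    def test_hand_computed_stepup(self):
        q = statcore.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_all_ones(self):
        assert statcore.bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.all(statcore.bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        p = rng.random(200) ** 2
        q = statcore.bh_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(50)
        perm = rng.permutation(50)
        assert np.allclose(statcore.bh_adjust(p)[perm],
                           statcore.bh_adjust(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            statcore.bh_adjust([0.5, 1.5])


class TestSpearman:
    def test_perfect_and_inverse(self):
        assert statcore.spearman_rho([1, 2, 3], [1, 2, 3]) == pytest.approx(1)
        assert statcore.spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1)

    def test_hand_computed(self):
        # 1 - 6*2/(4*15) = 0.8
        assert statcore.spearman_rho([1, 2, 3, 4],
                                     [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_returns_nan_marker(self):
        assert np.isnan(statcore.spearman_rho([1, 1, 1], [1, 2, 3]))


class TestDdct:
    def test_hand_computed_fold_change(self):
        # ddCt = (20-18) - (22-18) = -2 -> 2^2 = 4
        assert statcore.ddct_fold_change(20, 18, 22, 18) == pytest.approx(4.0)

    def test_equal_delta_ct_gives_unity(self):
        assert statcore.ddct_fold_change(21, 19, 25, 23) == pytest.approx(1.0)

    def test_one_cycle_halving(self):
        assert statcore.ddct_fold_change(21, 18, 20, 18) == pytest.approx(0.5)

    def test_invalid_ct_raises(self):
        with pytest.raises(ValueError):
            statcore.ddct_fold_change(-1, 18, 22, 18)
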