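import numpy as np
import pytest

from ptcascade.fit import (
    adjust_bh,
    build_spline_basis,
    fit_all_genes,
    fit_tobit_spline,
    scale_trajectory,
)
from ptcascade.fit import test_temporal_variation as temporal_variation_pvalue
from ptcascade.io import ExpressionMatrix, PseudotimeOrdering


def bh_oracle(p):
    """Independent step-up: q_(k) = cummin over descending rank of m*p_(k)/k."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        k = i + 1
        running = min(running, m * p[order[i]] / k)
        q[order[i]] = running
    return q


class TestSplineBasis:
    def test_shape_and_rank(self):
        b = build_spline_basis(np.arange(1.0, 11.0), df=2)
        assert b.matrix.shape == (10, 2)
        assert np.linalg.matrix_rank(b.matrix) == 2

    def test_degenerate_pseudotimes_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            build_spline_basis(np.ones(10), df=2)

    def test_df1_is_linear_column(self):
        t = np.arange(1.0, 11.0)
        b = build_spline_basis(t, df=1)
        assert b.matrix.shape == (10, 1)
        col = b.matrix[:, 0]
        assert np.all(np.diff(col) > 0)  # monotone linear trend
        np.testing.assert_allclose(np.diff(col), np.diff(col)[0])

    def test_evaluation_consistent_with_construction(self):
        t = np.linspace(0, 1, 50)
        b = build_spline_basis(t, df=2)
        np.testing.assert_allclose(b(t), b.matrix)


class TestTobit:
    def test_uncensored_fit_equals_least_squares(self, rng):
        # with no censored point the censored likelihood is the Gaussian
        # likelihood, whose MLE for the mean is ordinary least squares
        t = np.linspace(0, 1, 150)
        b = build_spline_basis(t, df=2)
        y = 5 + np.sin(3 * t) + rng.normal(0, 0.2, 150)
        assert y.min() > 0.1
        X = np.column_stack([np.ones(150), b.matrix])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        f = fit_tobit_spline(y, b, c=0.1)
        np.testing.assert_allclose(
            np.concatenate([[f.beta0], f.beta]), beta_ols, atol=1e-6
        )

    def test_censoring_correction_reduces_slope_bias(self):
        # clamping the lowest 20% of observations at the censor level
        # attenuates a naive Gaussian fit toward zero slope; the censored
        # likelihood recovers the true slope
        rng = np.random.default_rng(1234)
        t = np.linspace(0, 1, 200)
        y_lat = 1.0 + 0.5 * t + rng.normal(0, 0.1, 200)
        c = float(np.quantile(y_lat, 0.2))
        y = np.maximum(y_lat, c)
        b = build_spline_basis(t, df=1)
        f = fit_tobit_spline(y, b, c=c)
        slope = f.beta[0] / b._scale  # basis column is (t - mean)/scale
        assert abs(slope - 0.5) < 0.1
        naive = np.polyfit(t, y, 1)[0]
        assert abs(slope - 0.5) < abs(naive - 0.5)

    def test_fully_censored_gene_rejected(self):
        b = build_spline_basis(np.linspace(0, 1, 60), df=2)
        with pytest.raises(ValueError, match="censored"):
            fit_tobit_spline(np.full(60, 0.1), b, c=0.1)

    def test_nesting_loglik_full_at_least_null(self, small_fit):
        fits, _, _ = small_fit
        for f in fits.values():
            assert f.loglik_full >= f.loglik_null - 1e-6

    def test_raising_censor_above_data_matches_uncensored(self, rng):
        t = np.linspace(0, 1, 120)
        b = build_spline_basis(t, df=2)
        y = 3 + t + rng.normal(0, 0.2, 120)
        low = fit_tobit_spline(y, b, c=y.min() - 1.0)
        np.testing.assert_allclose(low.beta, fit_tobit_spline(y, b, c=0.1).beta, atol=1e-5)

    def test_shift_equivariance_of_scaled_trajectory(self, rng):
        t = np.linspace(0, 1, 120)
        b = build_spline_basis(t, df=2)
        y = 1 + 0.8 * t + rng.normal(0, 0.2, 120)
        k = 7.5
        f1 = fit_tobit_spline(y, b, c=-10)
        f2 = fit_tobit_spline(y + k, b, c=-10 + k)
        np.testing.assert_allclose(f2.predict(t), f1.predict(t) + k, atol=1e-4)
        s1, s2 = scale_trajectory(f1, t), scale_trajectory(f2, t)
        np.testing.assert_allclose(s1.x, s2.x, atol=1e-4)


class TestTemporalVariationTest:
    def test_type_i_error_near_nominal(self, rng):
        # flat genes: the LRT should reject at close to its nominal rate
        t = np.linspace(0, 1, 200)
        n_rej = 0
        reps = 400
        for _ in range(reps):
            y = 2.0 + rng.normal(0, 0.3, 200)
            if temporal_variation_pvalue(y, t) < 0.05:
                n_rej += 1
        assert 0.02 <= n_rej / reps <= 0.09

    def test_power_on_strong_monotone_gene(self, rng):
        t = np.linspace(0, 1, 200)
        y = 2 / (1 + np.exp(-(t - 0.5) / 0.05)) + rng.normal(0, 0.1, 200)
        assert temporal_variation_pvalue(y, t) < 1e-4

    def test_df_zero_gives_p_one(self, rng):
        y = rng.normal(2, 0.3, 100)
        assert temporal_variation_pvalue(y, np.linspace(0, 1, 100), df=0) == 1.0


class TestAdjustBH:
    def test_small_closed_form(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        np.testing.assert_allclose(adjust_bh([0.2]), [0.2])

    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(10):
            p = rng.uniform(size=1000)
            np.testing.assert_allclose(adjust_bh(p), bh_oracle(p), atol=1e-12)

    def test_monotonicity_and_domination(self, rng):
        p = rng.uniform(size=200)
        q = adjust_bh(p)
        assert np.all(q >= p) and np.all(q <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])


class TestScaleTrajectory:
    def test_hand_computed_standardization(self, rng):
        t = np.linspace(0, 1, 100)
        b = build_spline_basis(t, df=1)
        y = 1 + t + rng.normal(0, 0.05, 100)
        f = fit_tobit_spline(y, b, c=-5)
        grid = np.array([0.0, 0.5, 1.0])
        # linear fit: mu = (1, 1.5, 2)-ish -> standardized (-1.2247, 0, 1.2247)
        s = scale_trajectory(f, grid)
        np.testing.assert_allclose(s.x, [-1.2247, 0.0, 1.2247], atol=0.05)
        assert abs(s.x.mean()) < 1e-8 and abs(s.x.std() - 1) < 1e-6

    def test_constant_curve_rejected(self, rng):
        t = np.linspace(0, 1, 100)
        b = build_spline_basis(t, df=2)
        f = fit_tobit_spline(5 + rng.normal(0, 0.2, 100), b, c=0.1)
        f.beta[:] = 0.0
        with pytest.raises(ValueError, match="constant"):
            scale_trajectory(f, t)


class TestFitAllGenes:
    def test_signal_and_null_separation(self, rng):
        # 50 strong sigmoidal + 50 flat genes: high sensitivity, few nulls
        n_cells = 200
        t = np.sort(rng.uniform(0, 1, n_cells))
        vals = np.empty((100, n_cells))
        for i in range(50):
            vals[i] = 0.2 + 2 / (1 + np.exp(-(t - rng.uniform(0.2, 0.8)) / 0.05))
        for i in range(50, 100):
            vals[i] = 1.0
        vals += rng.normal(0, 0.3, vals.shape)
        vals[vals < 0.1] = 0.0
        m = ExpressionMatrix(vals, [f"g{i}" for i in range(100)], [f"c{i}" for i in range(n_cells)])
        ordering = PseudotimeOrdering(list(m.cell_ids), t)
        _, scaled = fit_all_genes(m, ordering)
        signal = sum(1 for g in scaled if int(g[1:]) < 50)
        flat = sum(1 for g in scaled if int(g[1:]) >= 50)
        assert signal >= 45  # sensitivity >= 0.9
        assert flat <= 5

    def test_alpha_one_retains_all_fitted(self, small_cascade):
        m, ords, _ = small_cascade
        fits, scaled = fit_all_genes(m, ords["s1"], alpha=1.0 + 1e-9)
        assert set(scaled) == set(fits)

    def test_empty_matrix_gives_empty_result(self):
        m = ExpressionMatrix(np.empty((0, 60)), [], [f"c{i}" for i in range(60)])
        ordering = PseudotimeOrdering(list(m.cell_ids), np.linspace(0, 1, 60))
        fits, scaled = fit_all_genes(m, ordering)
        assert fits == {} and scaled == {}

    def test_scaled_trajectories_standardized(self, small_fit):
        _, scaled, _ = small_fit
        for tr in scaled.values():
            assert abs(tr.x.mean()) < 1e-8
            assert abs(tr.x.std() - 1) < 1e-6
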