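import itertools

import numpy as np
import pytest

from quantgap import ProcessQuantileRegressor, check_loss, fit_process, fit_quantile
from quantgap.errors import SingularDesignError
from quantgap.regression import quantile_counts

SOLVERS = ("irls", "exact")


class TestCheckLoss:
    @pytest.mark.parametrize(
        "residuals,tau,expected",
        [([2.0], 0.9, 1.8), ([-2.0], 0.9, 0.2), ([-1.0, 1.0], 0.5, 1.0)],
    )
    def test_values(self, residuals, tau, expected):
        assert check_loss(residuals, tau) == pytest.approx(expected)

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.1, 1.5])
    def test_tau_domain(self, tau):
        with pytest.raises(ValueError):
            check_loss([1.0], tau)

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(20):
            u = rng.normal(size=rng.integers(1, 30))
            assert check_loss(u, float(rng.uniform(0.05, 0.95))) >= 0


class TestFitQuantile:
    @pytest.mark.parametrize("solver", SOLVERS)
    def test_intercept_only_median_is_sample_median(self, solver):
        X = np.ones((5, 1))
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        beta = fit_quantile(X, y, 0.5, solver=solver)
        assert beta[0] == pytest.approx(3.0, abs=1e-6)

    @pytest.mark.parametrize("solver", SOLVERS)
    @pytest.mark.parametrize("tau", [0.1, 0.5, 0.9])
    def test_two_points_interpolated_exactly(self, solver, tau):
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        y = np.array([0.0, 1.0])
        beta = fit_quantile(X, y, tau, solver=solver)
        assert beta == pytest.approx([0.0, 1.0], abs=1e-7)
        assert check_loss(y - X @ beta, tau) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("solver", SOLVERS)
    @pytest.mark.parametrize("tau", [0.25, 0.5, 0.8])
    def test_matches_brute_force_lattice(self, solver, tau):
        """On a tiny dataset the fitted loss equals the exhaustive lattice
        minimum over (intercept, slope) at step 0.01."""
        x = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        y = np.array([0.1, 0.8, 0.9, 2.1, 1.9, 3.2, 2.8])
        X = np.column_stack([np.ones(7), x])
        grid_b0 = np.arange(-1.0, 1.0, 0.01)
        grid_b1 = np.arange(0.0, 2.0, 0.01)
        best = min(
            check_loss(y - b0 - b1 * x, tau)
            for b0, b1 in itertools.product(grid_b0, grid_b1)
        )
        beta = fit_quantile(X, y, tau, solver=solver)
        fitted = check_loss(y - X @ beta, tau)
        # the exact LP is optimal to numerical precision; the smoothed IRLS
        # route is optimal up to its residual-smoothing tolerance
        tol = 1e-9 if solver == "exact" else 5e-5 * best
        assert fitted <= best + tol

    @pytest.mark.parametrize("solver", SOLVERS)
    def test_loss_no_worse_than_least_squares(self, solver, small_dataset):
        X, y = small_dataset
        ls = np.linalg.lstsq(X, y, rcond=None)[0]
        for tau in (0.1, 0.5, 0.9):
            beta = fit_quantile(X, y, tau, solver=solver)
            assert check_loss(y - X @ beta, tau) <= check_loss(y - X @ ls, tau) + 1e-9

    @pytest.mark.parametrize("solver", SOLVERS)
    def test_subgradient_residual_counts(self, solver, small_dataset):
        """At an optimum #{r<0} <= n*tau <= #{r<=0}, up to solver tolerance."""
        X, y = small_dataset
        n, p = X.shape
        scale = np.max(np.abs(y))
        for tau in (0.2, 0.5, 0.8):
            beta = fit_quantile(X, y, tau, solver=solver)
            neg, nonpos = quantile_counts(y - X @ beta, tau, zero_tol=1e-6 * scale)
            slack = 0 if solver == "exact" else p
            assert neg <= n * tau + slack
            assert nonpos >= n * tau - slack

    def test_equivariance_scale_and_shift(self, small_dataset):
        X, y = small_dataset
        b = fit_quantile(X, y, 0.3)
        b_scaled = fit_quantile(X, 2.5 * y, 0.3)
        assert b_scaled == pytest.approx(2.5 * b, rel=1e-4, abs=1e-5)
        b_shift = fit_quantile(X, y + 7.0, 0.3)
        assert b_shift[0] == pytest.approx(b[0] + 7.0, rel=1e-4)
        assert b_shift[1:] == pytest.approx(b[1:], rel=1e-3, abs=1e-5)

    def test_agrees_with_statsmodels(self, small_dataset):
        sm = pytest.importorskip("statsmodels.api")
        X, y = small_dataset
        for tau in (0.25, 0.5, 0.75):
            ours = fit_quantile(X, y, tau, solver="irls")
            ref = sm.QuantReg(y, X).fit(q=tau).params
            assert ours == pytest.approx(np.asarray(ref), abs=2e-3)

    def test_exact_and_irls_agree_in_loss(self, small_dataset):
        X, y = small_dataset
        for tau in (0.2, 0.8):
            l_irls = check_loss(y - X @ fit_quantile(X, y, tau, solver="irls"), tau)
            l_lp = check_loss(y - X @ fit_quantile(X, y, tau, solver="exact"), tau)
            assert l_irls <= l_lp * (1 + 1e-5) + 1e-9

    def test_rank_deficient_design_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(SingularDesignError, match="collinear"):
            fit_quantile(X, np.arange(10.0), 0.5, column_names=["const", "a", "b"])

    def test_deterministic(self, small_dataset):
        X, y = small_dataset
        assert np.array_equal(
            fit_quantile(X, y, 0.4), fit_quantile(X, y, 0.4)
        )


class TestFitProcess:
    def test_intercept_only_reduces_to_sample_quantiles(self):
        y = np.arange(1.0, 6.0)
        fit = fit_process(np.ones((5, 1)), y, (0.25, 0.5, 0.75))
        # with n=5 the sample tau-quantile is an order statistic at these taus
        expected = np.quantile(y, [0.25, 0.5, 0.75])
        assert fit.coef[:, 0] == pytest.approx(expected, abs=1e-6)

    def test_rows_match_single_fits(self, small_dataset):
        X, y = small_dataset
        taus = (0.2, 0.5, 0.8)
        fit = fit_process(X, y, taus)
        for m, tau in enumerate(taus):
            assert fit.coef[m] == pytest.approx(fit_quantile(X, y, tau), abs=1e-12)

    def test_grid_order_independence(self, small_dataset):
        X, y = small_dataset
        a = fit_process(X, y, (0.2, 0.5, 0.8)).coef
        b = fit_process(X, y, (0.8, 0.2, 0.5)).coef
        assert a[0] == pytest.approx(b[1], abs=1e-12)
        assert a[2] == pytest.approx(b[0], abs=1e-12)

    def test_empty_grid_is_empty_fit(self, small_dataset):
        X, y = small_dataset
        fit = fit_process(X, y, ())
        assert fit.coef.shape == (0, X.shape[1])
        assert fit.objective.size == 0

    def test_recovers_location_scale_truth(self):
        from scipy.stats import norm

        from quantgap.simulate import RECOVERY_DGP, generate_group
        from dataclasses import replace

        dgp = replace(RECOVERY_DGP, n=2000)
        sample = generate_group(dgp, 42)
        taus = np.linspace(0.1, 0.9, 9)
        fit = fit_process(sample.design, sample.outcome, taus)
        truth = np.asarray(dgp.beta) + np.outer(norm.ppf(taus), dgp.gamma)
        assert np.max(np.abs(fit.coef - truth)) < 0.2


class TestProcessQuantileRegressor:
    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = ProcessQuantileRegressor(taus=(0.5,), solver="exact")
        cloned = clone(est)
        assert cloned.get_params()["solver"] == "exact"

    def test_fit_predict_shapes(self, small_dataset):
        X, y = small_dataset
        est = ProcessQuantileRegressor(taus=(0.25, 0.5, 0.75)).fit(X[:, 1:], y)
        assert est.coef_.shape == (3, 2)
        assert est.predict(X[:5, 1:]).shape == (5, 3)
        assert est.predict(X[:5, 1:], tau=0.5).shape == (5,)
        with pytest.raises(ValueError):
            est.predict(X[:5, 1:], tau=0.33)

    def test_unfitted_predict_raises(self, small_dataset):
        X, y = small_dataset
        with pytest.raises(AttributeError):
            ProcessQuantileRegressor().predict(X[:, 1:])

    def test_median_predictions_match_fit_quantile(self, small_dataset):
        X, y = small_dataset
        est = ProcessQuantileRegressor(taus=(0.5,)).fit(X[:, 1:], y)
        direct = fit_quantile(X, y, 0.5)
        assert est.intercept_[0] == pytest.approx(direct[0], abs=1e-9)
        assert est.coef_[0] == pytest.approx(direct[1:], abs=1e-9)
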