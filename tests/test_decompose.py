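import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quantgap import (
    aggregate_decompose,
    contribution_percent,
    detailed_decompose,
    marginal_qf,
    rearrange_monotone,
)
from quantgap.regression import QuantileProcessFit, fit_group_process


def make_fit(label, taus, coef):
    coef = np.asarray(coef, dtype=float)
    return QuantileProcessFit(label, np.asarray(taus), coef, np.zeros(len(taus)))


class TestRearrange:
    @pytest.mark.parametrize(
        "values,expected",
        [((1, 2, 3), (1, 2, 3)), ((3, 1, 2), (1, 2, 3)), ((2.0,), (2.0,))],
    )
    def test_examples(self, values, expected):
        assert rearrange_monotone(values) == pytest.approx(np.asarray(expected))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    def test_preserves_multiset_and_sorts(self, values):
        out = rearrange_monotone(values)
        assert sorted(values) == pytest.approx(list(out))
        assert np.all(np.diff(out) >= 0)


class TestMarginalQF:
    def test_degenerate_pool_is_constant(self):
        fit = make_fit("g", (0.25, 0.5, 0.75), [[5.0, 0.0]] * 3)
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        X[:, 1] = 0.0
        qf = marginal_qf(fit, X, (0.1, 0.5, 0.9))
        assert qf.values == pytest.approx([5.0, 5.0, 5.0])

    def test_single_row_pooled_median(self):
        fit = make_fit("g", (0.25, 0.5, 0.75), [[1.0], [2.0], [3.0]])
        qf = marginal_qf(fit, np.ones((1, 1)), (0.5,))
        assert qf.values[0] == pytest.approx(2.0)

    def test_width_mismatch_raises(self):
        fit = make_fit("g", (0.5,), [[1.0, 2.0]])
        with pytest.raises(ValueError, match="width"):
            marginal_qf(fit, np.ones((4, 3)), (0.5,))

    def test_values_within_pool_range(self, rng):
        coef = rng.normal(size=(7, 3))
        fit = make_fit("g", np.linspace(0.1, 0.9, 7), coef)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        qf = marginal_qf(fit, X, np.linspace(0.05, 0.95, 9))
        pool = fit.predict(X).ravel()
        assert np.all(qf.values >= pool.min() - 1e-12)
        assert np.all(qf.values <= pool.max() + 1e-12)

    def test_matches_direct_pool_quantiles(self, rng):
        coef = rng.normal(size=(5, 2))
        fit = make_fit("g", np.linspace(0.1, 0.9, 5), coef)
        X = np.column_stack([np.ones(8), rng.normal(size=8)])
        qf = marginal_qf(fit, X, (0.3, 0.6))
        pool = (X @ coef.T).ravel()
        assert qf.raw_values == pytest.approx(np.quantile(pool, [0.3, 0.6]))


class TestAggregateDecompose:
    def test_self_comparison_is_identically_zero(self, small_groups):
        ref, _ = small_groups
        taus = np.linspace(0.05, 0.95, 19)
        fit = fit_group_process(ref, taus)
        agg = aggregate_decompose(fit, fit, ref.design, ref.design, (0.1, 0.5, 0.9))
        assert np.all(agg.difference == 0)
        assert np.all(agg.covariates_part == 0)
        assert np.all(agg.coefficients_part == 0)

    def test_additivity_exact(self, small_groups, small_spec):
        ref, cmp_ = small_groups
        taus = small_spec.tau_grid
        fr = fit_group_process(ref, taus)
        fc = fit_group_process(cmp_, taus)
        agg = aggregate_decompose(fr, fc, ref.design, cmp_.design, small_spec.report_taus)
        assert agg.covariates_part + agg.coefficients_part == pytest.approx(
            agg.difference, abs=1e-9
        )

    def test_pure_intercept_shift_forces_parts(self):
        """Same design and coefficient process apart from a unit intercept
        shift: the covariates part is exactly 0, the coefficients part 1."""
        taus = np.linspace(0.1, 0.9, 9)
        rng = np.random.default_rng(5)
        coef = np.cumsum(rng.uniform(0.1, 0.3, size=(9, 2)), axis=0)
        fit_ref = make_fit("ref", taus, coef + np.array([1.0, 0.0]))
        fit_cmp = make_fit("cmp", taus, coef)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        agg = aggregate_decompose(fit_ref, fit_cmp, X, X, (0.25, 0.5, 0.75))
        assert agg.covariates_part == pytest.approx(np.zeros(3), abs=1e-12)
        assert agg.coefficients_part == pytest.approx(np.ones(3), abs=1e-12)

    def test_swapping_reference_negates_difference(self, small_groups, small_spec):
        ref, cmp_ = small_groups
        taus = small_spec.tau_grid
        fr = fit_group_process(ref, taus)
        fc = fit_group_process(cmp_, taus)
        fwd = aggregate_decompose(fr, fc, ref.design, cmp_.design, small_spec.report_taus)
        rev = aggregate_decompose(fc, fr, cmp_.design, ref.design, small_spec.report_taus)
        assert rev.difference == pytest.approx(-fwd.difference, abs=1e-12)

    def test_grid_mismatch_raises(self, small_groups):
        ref, cmp_ = small_groups
        fr = fit_group_process(ref, (0.25, 0.5))
        fc = fit_group_process(cmp_, (0.25, 0.75))
        with pytest.raises(ValueError, match="grid"):
            aggregate_decompose(fr, fc, ref.design, cmp_.design, (0.5,))


class TestDetailedDecompose:
    def test_intercept_only_gap_lands_on_intercept(self):
        taus = np.array([0.25, 0.5, 0.75])
        gap = np.array([1.0, 2.0, 3.0])
        base = np.array([5.0, 6.0, 7.0])
        fit_ref = make_fit("ref", taus, (base + gap)[:, None])
        fit_cmp = make_fit("cmp", taus, base[:, None])
        X = np.ones((10, 1))
        agg = aggregate_decompose(fit_ref, fit_cmp, X, X, taus)
        det = detailed_decompose(fit_ref, fit_cmp, X, X, agg)
        assert det.coefficients_detail[:, 0] == pytest.approx(gap)
        assert det.covariates_detail == pytest.approx(np.zeros((3, 1)))
        assert det.covariates_remainder == pytest.approx(np.zeros(3), abs=1e-12)
        assert det.coefficients_remainder == pytest.approx(np.zeros(3), abs=1e-12)

    def test_equal_covariate_means_zero_covariate_details(self, rng):
        taus = np.array([0.5])
        fit_ref = make_fit("ref", taus, [[1.0, 2.0, 3.0]])
        fit_cmp = make_fit("cmp", taus, [[0.5, 1.0, 1.5]])
        Z = rng.normal(size=(12, 2))
        Xr = np.column_stack([np.ones(12), Z])
        Xc = np.column_stack([np.ones(12), Z[::-1]])  # same means
        agg = aggregate_decompose(fit_ref, fit_cmp, Xr, Xc, taus)
        det = detailed_decompose(fit_ref, fit_cmp, Xr, Xc, agg)
        assert det.covariates_detail[0, 1:] == pytest.approx(np.zeros(2), abs=1e-12)

    def test_two_covariate_terms_match_hand_computation(self, small_groups):
        ref, cmp_ = small_groups
        taus = np.array([0.25, 0.5, 0.75])
        fr = fit_group_process(ref, taus)
        fc = fit_group_process(cmp_, taus)
        agg = aggregate_decompose(fr, fc, ref.design, cmp_.design, taus)
        det = detailed_decompose(fr, fc, ref.design, cmp_.design, agg)
        xbar_r = ref.design.mean(axis=0)
        xbar_c = cmp_.design.mean(axis=0)
        for k in range(3):
            expected_cov = (xbar_r - xbar_c) * fr.coef[k]
            expected_coef = xbar_c * (fr.coef[k] - fc.coef[k])
            assert det.covariates_detail[k] == pytest.approx(expected_cov, abs=1e-9)
            assert det.coefficients_detail[k] == pytest.approx(expected_coef, abs=1e-9)
        # details plus remainder reconstruct the aggregate parts exactly
        assert det.covariates_detail.sum(axis=1) + det.covariates_remainder == (
            pytest.approx(agg.covariates_part, abs=1e-9)
        )
        assert det.coefficients_detail.sum(axis=1) + det.coefficients_remainder == (
            pytest.approx(agg.coefficients_part, abs=1e-9)
        )


class TestContributionPercent:
    @pytest.mark.parametrize(
        "part,diff,expected",
        [(17.1, 21.3, 80.3), (0.0, 5.0, 0.0), (7.0, 7.0, 100.0)],
    )
    def test_values(self, part, diff, expected):
        assert contribution_percent(part, diff) == pytest.approx(expected, abs=0.05)

    def test_zero_difference_is_nan_not_error(self):
        assert np.isnan(contribution_percent(1.0, 0.0))
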