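import numpy as np
import pytest

from quantgap import classify_quantile, detect_countervailing, render_strategy_report
from quantgap.datasets import example_decomposition_table
from quantgap.decompose import AggregateDecomposition, DetailedDecomposition
from quantgap.strategy import classify_decomposition
from quantgap.errors import QuantgapError


def classify_table_rows(table):
    out = []
    for _, row in table.iterrows():
        out.append(
            classify_quantile(
                row["tau"],
                row["covariates_part"],
                row["coefficients_part"],
                row["difference"],
                (row["covariates_lo"], row["covariates_hi"]),
                (row["coefficients_lo"], row["coefficients_hi"]),
            )
        )
    return out


class TestClassifyQuantile:
    def test_published_example_indications(self):
        """On the published demonstration table: coefficients part dominant
        at every quantile; covariates part the only significant one at the
        lowest quantile (supplementary proportionate universalism), the
        coefficients part alone significant at Q25/Q50, both at Q75/Q90."""
        inds = classify_table_rows(example_decomposition_table())
        assert [i.dominant_part for i in inds] == ["coefficients"] * 5
        assert [i.indication for i in inds] == [
            "proportionate_universalism", "targeted", "targeted",
            "combined", "combined",
        ]
        assert [i.covariates_significant for i in inds] == [
            True, False, False, True, True,
        ]

    def test_zero_disparity_is_none(self):
        ind = classify_quantile(0.5, 0.0, 0.0, 0.0, (-1.0, 1.0), (-1.0, 1.0))
        assert ind.indication == "none"
        assert ind.dominant_part == "none"
        assert np.isnan(ind.covariates_share)

    def test_without_cis_falls_back_to_dominance(self):
        ind = classify_quantile(0.5, 3.0, 1.0, 4.0)
        assert ind.covariates_significant is None
        assert ind.indication == "proportionate_universalism"

    def test_positive_rescaling_invariance(self):
        a = classify_quantile(0.5, 2.0, 6.0, 8.0, (0.5, 3.5), (2.0, 10.0))
        b = classify_quantile(0.5, 20.0, 60.0, 80.0, (5.0, 35.0), (20.0, 100.0))
        assert a.indication == b.indication == "combined"
        assert a.covariates_share == pytest.approx(b.covariates_share)

    def test_missing_ci_with_reps_is_error(self):
        agg = _zero_agg()
        with pytest.raises(QuantgapError):
            classify_decomposition(agg, None, reps=10)


def _zero_agg(taus=(0.25, 0.5, 0.75)):
    z = np.zeros(len(taus))
    return AggregateDecomposition(
        report_taus=np.asarray(taus), q_reference=z, q_comparison=z,
        q_counterfactual=z, difference=z.copy(), covariates_part=z.copy(),
        coefficients_part=z.copy(),
    )


def _detail(taus, names, cov, coef):
    cov = np.asarray(cov, dtype=float)
    coef = np.asarray(coef, dtype=float)
    return DetailedDecomposition(
        report_taus=np.asarray(taus), column_names=names,
        covariates_detail=cov, coefficients_detail=coef,
        covariates_remainder=np.zeros(len(taus)),
        coefficients_remainder=np.zeros(len(taus)),
    )


class TestCountervailing:
    names = ["const", "income"]

    def test_same_sign_details_flagged(self):
        det = _detail([0.5], self.names, [[0.0, 2.0]], [[1.0, 5.0]])
        flags = detect_countervailing(det, gap_sign=1, difference=[20.0])
        assert [f.covariate for f in flags] == ["income"]
        assert flags[0].taus == [0.5]
        assert "structural" in flags[0].note

    def test_opposite_signs_not_flagged(self):
        det = _detail([0.5], self.names, [[0.0, 2.0]], [[1.0, -5.0]])
        assert detect_countervailing(det, gap_sign=1, difference=[20.0]) == []

    def test_below_floor_not_flagged(self):
        det = _detail([0.5], self.names, [[0.0, 0.1]], [[1.0, 0.1]])
        assert detect_countervailing(det, gap_sign=1, difference=[20.0]) == []

    def test_intercept_never_flagged(self):
        det = _detail([0.5], self.names, [[5.0, 0.0]], [[5.0, 0.0]])
        flags = detect_countervailing(det, gap_sign=1, difference=[20.0])
        assert all(f.covariate != "const" for f in flags)

    def test_negative_floor_rejected(self):
        det = _detail([0.5], self.names, [[0.0, 2.0]], [[1.0, 5.0]])
        with pytest.raises(ValueError):
            detect_countervailing(det, gap_sign=1, floor=-1.0)


class TestRenderReport:
    def test_all_zero_reports_no_disparity(self):
        agg = _zero_agg()
        det = _detail(
            agg.report_taus, ["const"], np.zeros((3, 1)), np.zeros((3, 1))
        )
        inds = classify_decomposition(agg, None, reps=0)
        report = render_strategy_report(inds, [], agg, det)
        assert "No disparity detected" in report.summary
        assert report.caveats == []

    def test_intercept_dominance_triggers_unmeasured_factors_caveat(self):
        taus = np.array([0.5])
        agg = AggregateDecomposition(
            report_taus=taus, q_reference=np.array([10.0]),
            q_comparison=np.array([4.0]), q_counterfactual=np.array([9.0]),
            difference=np.array([6.0]), covariates_part=np.array([1.0]),
            coefficients_part=np.array([5.0]),
        )
        det = _detail(taus, ["const", "income"], [[0.0, 1.0]], [[4.0, 1.0]])
        inds = classify_decomposition(agg, None, reps=0)
        report = render_strategy_report(inds, [], agg, det)
        assert any("unmeasured factors" in c for c in report.caveats)

    def test_published_table_dominance_summary(self):
        table = example_decomposition_table()
        inds = classify_table_rows(table)
        taus = table["tau"].to_numpy()
        agg = AggregateDecomposition(
            report_taus=taus,
            q_reference=table["q_reference"].to_numpy(),
            q_comparison=table["q_comparison"].to_numpy(),
            q_counterfactual=table["q_reference"].to_numpy()
            - table["covariates_part"].to_numpy(),
            difference=table["difference"].to_numpy(),
            covariates_part=table["covariates_part"].to_numpy(),
            coefficients_part=table["coefficients_part"].to_numpy(),
        )
        det = _detail(taus, ["const"], np.zeros((5, 1)), np.zeros((5, 1)))
        report = render_strategy_report(inds, [], agg, det)
        assert all(i.dominant_part == "coefficients" for i in report.indications)
        assert report.to_dict()["quantiles"][0]["indication"] == (
            "proportionate_universalism"
        )

    def test_rendering_deterministic(self):
        agg = _zero_agg()
        det = _detail(agg.report_taus, ["const"], np.zeros((3, 1)), np.zeros((3, 1)))
        inds = classify_decomposition(agg, None, reps=0)
        r1 = render_strategy_report(inds, [], agg, det)
        r2 = render_strategy_report(inds, [], agg, det)
        assert r1.to_json() == r2.to_json()
        assert r1.to_text() == r2.to_text()
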