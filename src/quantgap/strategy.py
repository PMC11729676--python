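"""Mapping decomposition output onto population-health strategies.

The covariates part of a quantile gap is the portion a *proportionate
universalist* program can act on: the groups respond alike, they differ in
risk-factor levels, so universal action with intensity proportional to
disadvantage closes it.  The coefficients part signals heterogeneous
risk-outcome responses, calling for a *targeted* (vulnerable-population)
approach.  Classification at each reported quantile is driven by which
parts' confidence intervals exclude zero; the dominant part (larger
absolute contribution share) is recorded alongside.

A covariate is flagged as *countervailing* when its level gap closes part
of the disparity while the response gap runs the same way — then simply
raising the disadvantaged group's level of that covariate would be blunted
(or reversed) by their weaker response, and a response-modifying
("structural") intervention is indicated instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .decompose import AggregateDecomposition, DetailedDecomposition, contribution_percent
from .bootstrap import BootstrapResult
from .errors import QuantgapError

__all__ = [
    "classify_quantile",
    "detect_countervailing",
    "render_strategy_report",
    "StrategyIndication",
    "CountervailingFlag",
    "StrategyReport",
]

DOMINANCE_SHARE = 50.0  # percent; declared convention, not an inferred fact
COUNTERVAIL_FLOOR_FRACTION = 0.01  # of |difference| at the same tau
INTERCEPT_CAVEAT_FRACTION = 0.5  # intercept share of coefficients part


@dataclass
class StrategyIndication:
    tau: float
    dominant_part: str  # {"covariates", "coefficients", "none"}
    covariates_significant: Optional[bool]
    coefficients_significant: Optional[bool]
    indication: str  # {"targeted", "proportionate_universalism", "combined", "none"}
    covariates_share: float
    coefficients_share: float

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "dominant_part": self.dominant_part,
            "covariates_significant": self.covariates_significant,
            "coefficients_significant": self.coefficients_significant,
            "indication": self.indication,
            "covariates_share_pct": self.covariates_share,
            "coefficients_share_pct": self.coefficients_share,
        }


@dataclass
class CountervailingFlag:
    covariate: str
    taus: List[float]
    note: str

    def to_dict(self) -> dict:
        return {"covariate": self.covariate, "taus": self.taus, "note": self.note}


def _excludes_zero(lo, hi) -> bool:
    return bool(lo > 0 or hi < 0)


def classify_quantile(
    tau: float,
    covariates_part: float,
    coefficients_part: float,
    difference: float,
    covariates_ci=None,
    coefficients_ci=None,
) -> StrategyIndication:
    """Strategy indication at one quantile.

    Significance (CI excluding 0) decides the indication: both parts
    significant -> "combined"; only the covariates part -> proportionate
    universalism; only the coefficients part -> targeted; neither ->
    "none".  Dominance (share of the absolute contribution above 50%) is
    recorded regardless of significance.  Without CIs (reps = 0) the
    significance fields are None and the indication falls back to the
    dominant part.
    """
    cov_share = contribution_percent(covariates_part, difference)
    coef_share = contribution_percent(coefficients_part, difference)
    if difference == 0 and covariates_part == 0 and coefficients_part == 0:
        dominant = "none"
    elif abs(covariates_part) > abs(coefficients_part):
        dominant = "covariates"
    elif abs(coefficients_part) > abs(covariates_part):
        dominant = "coefficients"
    else:
        dominant = "none"

    if covariates_ci is None or coefficients_ci is None:
        cov_sig = coef_sig = None
        indication = {
            "covariates": "proportionate_universalism",
            "coefficients": "targeted",
            "none": "none",
        }[dominant]
    else:
        cov_sig = _excludes_zero(*covariates_ci)
        coef_sig = _excludes_zero(*coefficients_ci)
        if cov_sig and coef_sig:
            indication = "combined"
        elif cov_sig:
            indication = "proportionate_universalism"
        elif coef_sig:
            indication = "targeted"
        else:
            indication = "none"
    return StrategyIndication(
        tau=float(tau),
        dominant_part=dominant,
        covariates_significant=cov_sig,
        coefficients_significant=coef_sig,
        indication=indication,
        covariates_share=cov_share,
        coefficients_share=coef_share,
    )


def classify_decomposition(
    agg: AggregateDecomposition, ci: Optional[BootstrapResult] = None, reps: int = 0
) -> List[StrategyIndication]:
    """Classify every reported quantile of a decomposition."""
    if ci is None and reps > 0:
        raise QuantgapError(
            "bootstrap intervals are required for classification when reps > 0"
        )
    out = []
    for k, tau in enumerate(agg.report_taus):
        if ci is not None and ci.lower is not None:
            cov_ci = (ci.lower["covariates_part"][k], ci.upper["covariates_part"][k])
            coef_ci = (
                ci.lower["coefficients_part"][k],
                ci.upper["coefficients_part"][k],
            )
        else:
            cov_ci = coef_ci = None
        out.append(
            classify_quantile(
                tau,
                agg.covariates_part[k],
                agg.coefficients_part[k],
                agg.difference[k],
                cov_ci,
                coef_ci,
            )
        )
    return out


def detect_countervailing(
    detail: DetailedDecomposition,
    gap_sign: int,
    floor=None,
    difference=None,
) -> List[CountervailingFlag]:
    """Flag covariates whose level and response contributions both carry
    the gap's sign above a noise floor.

    ``floor`` may be a scalar (outcome units) or None, in which case it
    defaults to 1% of |difference| at each tau (``difference`` required
    then).  The intercept is never flagged: it is not an intervenable
    covariate.
    """
    if floor is not None and np.any(np.asarray(floor) < 0):
        raise ValueError("floor must be non-negative")
    K = detail.report_taus.size
    if floor is None:
        if difference is None:
            raise ValueError("difference is required when floor is None")
        floors = COUNTERVAIL_FLOOR_FRACTION * np.abs(np.asarray(difference, dtype=float))
    else:
        floors = np.full(K, float(floor))
    flags = []
    for j, name in enumerate(detail.column_names):
        if j == 0:
            continue  # intercept
        taus_hit = []
        for k in range(K):
            cov = detail.covariates_detail[k, j]
            coef = detail.coefficients_detail[k, j]
            if (
                np.sign(cov) == gap_sign
                and np.sign(coef) == gap_sign
                and abs(cov) > floors[k]
                and abs(coef) > floors[k]
            ):
                taus_hit.append(float(detail.report_taus[k]))
        if taus_hit:
            flags.append(
                CountervailingFlag(
                    covariate=name,
                    taus=taus_hit,
                    note=(
                        f"Equalising the level of '{name}' closes part of the gap, "
                        "but the comparison group's weaker response would blunt a "
                        "level-raising intervention; consider modifying the "
                        "response (structural intervention) instead."
                    ),
                )
            )
    return flags


@dataclass
class StrategyReport:
    indications: List[StrategyIndication]
    flags: List[CountervailingFlag]
    caveats: List[str] = field(default_factory=list)
    summary: str = ""

    def to_dict(self) -> dict:
        return {
            "quantiles": [i.to_dict() for i in self.indications],
            "countervailing_flags": [f.to_dict() for f in self.flags],
            "caveats": self.caveats,
            "summary": self.summary,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_text(self) -> str:
        lines = [self.summary, ""]
        for ind in self.indications:
            sig = []
            if ind.covariates_significant:
                sig.append("covariates part significant")
            if ind.coefficients_significant:
                sig.append("coefficients part significant")
            lines.append(
                f"tau={ind.tau:.2f}: indication={ind.indication} "
                f"(dominant part: {ind.dominant_part}; "
                f"shares cov {ind.covariates_share:.1f}% / "
                f"coef {ind.coefficients_share:.1f}%"
                + ("; " + ", ".join(sig) if sig else "")
                + ")"
            )
        if self.flags:
            lines.append("")
            lines.append("Countervailing covariates:")
            for f in self.flags:
                lines.append(f"- {f.covariate} at taus {f.taus}: {f.note}")
        if self.caveats:
            lines.append("")
            lines.append("Caveats:")
            lines.extend(f"- {c}" for c in self.caveats)
        return "\n".join(lines)


def render_strategy_report(
    indications: List[StrategyIndication],
    flags: List[CountervailingFlag],
    agg: AggregateDecomposition,
    detail: DetailedDecomposition,
) -> StrategyReport:
    """Assemble the machine- and human-readable strategy report."""
    if len(indications) != agg.report_taus.size:
        raise ValueError("indications and aggregate report_taus are inconsistent")
    caveats = []
    if np.all(agg.difference == 0):
        summary = "No disparity detected: the group quantile functions coincide."
    else:
        seg = {}
        for ind in indications:
            seg.setdefault(ind.indication, []).append(f"{ind.tau:.2f}")
        parts = [
            f"{name} at tau {{{', '.join(ts)}}}" for name, ts in seg.items()
        ]
        summary = "Indicated strategy mix: " + "; ".join(parts) + "."
    # unmeasured-factors caveat: intercept dominates the coefficients part
    for k, tau in enumerate(agg.report_taus):
        part = agg.coefficients_part[k]
        intercept_term = detail.coefficients_detail[k, 0]
        if part != 0 and abs(intercept_term) > INTERCEPT_CAVEAT_FRACTION * abs(part):
            caveats.append(
                f"At tau={tau:.2f} the regression constant drives more than half "
                "of the coefficients part: unmeasured factors may explain the "
                "disparity at this quantile."
            )
    return StrategyReport(
        indications=indications, flags=flags, caveats=caveats, summary=summary
    )
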