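"""Percentile-bootstrap pointwise confidence intervals.

Resampling is done with replacement *within* each group (groups are
strata, so group sizes are fixed), the whole pipeline — quantile process
fits, aggregate and detailed decomposition — is re-run on every replicate,
and pointwise intervals are the empirical ((1-level)/2, 1-(1-level)/2)
quantiles of the replicate draws.

A replicate is encoded as an integer row-multiplicity vector, which lets
all replicates of a group be fitted in one batched IRLS call; the
decomposition of each replicate then uses the correspondingly expanded
design matrices, so both the coefficient processes *and* the covariate
distributions are resampled, as in resampling rows of the raw data.

A single root seed spawns one child stream per replicate
(``numpy.random.SeedSequence.spawn``), so increasing ``reps`` extends the
replicate set without reshuffling earlier replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

from .decompose import aggregate_decompose, detailed_decompose
from .errors import InferenceError
from .io import AnalysisSpec, GroupSample
from .regression import _irls_batch, QuantileProcessFit, check_loss

__all__ = [
    "percentile_interval",
    "bootstrap_decomposition",
    "dump_draws",
    "BootstrapResult",
]


def dump_draws(result: "BootstrapResult", path) -> None:
    """Write the raw per-quantile bootstrap draws to a delimited file for
    audit (one row per replicate, one column per quantity x tau)."""
    import pandas as pd

    if not result.draws:
        raise InferenceError("no bootstrap draws stored (reps == 0)")
    cols = {}
    for name in ("difference", "covariates_part", "coefficients_part"):
        for k, tau in enumerate(result.report_taus):
            cols[f"{name}_q{int(round(tau * 100))}"] = result.draws[name][:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def percentile_interval(samples, level: float):
    """Empirical percentile interval of bootstrap draws.

    Returns the ((1-level)/2, 1-(1-level)/2) empirical quantiles under the
    package-wide linear-interpolation convention.
    """
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise InferenceError("cannot form a percentile interval from no samples")
    if not 0 < level < 1:
        raise InferenceError(f"confidence level must lie in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(s, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class BootstrapResult:
    """Point estimates, percentile bounds and raw draws per quantity.

    ``draws[name]`` has shape (reps_used, ...) matching the point
    estimate's shape; ``lower``/``upper`` are None when ``reps == 0``.
    """

    reps: int
    seed: int
    ci_level: float
    report_taus: np.ndarray
    point: dict
    lower: Optional[dict]
    upper: Optional[dict]
    draws: dict = field(default_factory=dict)
    n_failed: int = 0
    column_names: list = field(default_factory=list)

    def interval(self, name: str, level: Optional[float] = None):
        """(lower, upper) arrays for a quantity, optionally at another level
        computed from the same stored draws."""
        if not self.draws:
            raise InferenceError("no bootstrap draws stored (reps == 0)")
        level = self.ci_level if level is None else level
        d = self.draws[name]
        alpha = (1.0 - level) / 2.0
        return (
            np.quantile(d, alpha, axis=0),
            np.quantile(d, 1.0 - alpha, axis=0),
        )


_AGG_KEYS = ("difference", "covariates_part", "coefficients_part",
             "q_reference", "q_comparison")


def _replicate_counts(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.multinomial(n, np.full(n, 1.0 / n)).astype(float)


def _expand(design: np.ndarray, counts: np.ndarray) -> np.ndarray:
    return np.repeat(design, counts.astype(int), axis=0)


def _counts_rank_ok(design: np.ndarray, counts: np.ndarray) -> bool:
    sub = design[counts > 0]
    return np.linalg.matrix_rank(sub) == design.shape[1]


def bootstrap_decomposition(
    reference: GroupSample,
    comparison: GroupSample,
    spec: AnalysisSpec,
    max_iter: int = 300,
    fits=None,
) -> BootstrapResult:
    """Bootstrap the full decomposition pipeline.

    Parameters
    ----------
    reference, comparison : GroupSample
        The two analysis groups (reference = coefficients donor).
    spec : AnalysisSpec
        Supplies tau_grid, report_taus, bootstrap_reps, ci_level, seed and
        solver settings.
    fits : optional pair of QuantileProcessFit
        Pre-computed point-estimate fits (to avoid refitting).

    Replicates whose resampled design is rank deficient are dropped and
    counted; more than 10% failures raises :class:`InferenceError`.
    """
    taus = np.asarray(spec.tau_grid, dtype=float)
    report = np.asarray(spec.report_taus, dtype=float)
    reps = int(spec.bootstrap_reps)

    groups = {"ref": reference, "cmp": comparison}
    # replicate count vectors from per-replicate spawned substreams
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(reps)
    counts = {k: np.empty((reps, g.n)) for k, g in groups.items()}
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        counts["ref"][r] = _replicate_counts(rng, reference.n)
        counts["cmp"][r] = _replicate_counts(rng, comparison.n)

    ok = np.ones(reps, dtype=bool)
    for k, g in groups.items():
        for r in range(reps):
            if ok[r] and not _counts_rank_ok(g.design, counts[k][r]):
                ok[r] = False
    n_failed = int(reps - ok.sum())
    if reps and n_failed > 0.10 * reps:
        raise InferenceError(
            f"{n_failed}/{reps} bootstrap replicates had rank-deficient "
            "resampled designs"
        )

    # batched fit: row 0 is the point estimate (unit weights)
    B = {}
    for k, g in groups.items():
        all_counts = np.vstack([np.ones((1, g.n)), counts[k][ok]])
        if spec.solver == "exact":
            from .regression import _fit_lp

            stack = np.empty((all_counts.shape[0], taus.size, g.width))
            for r in range(all_counts.shape[0]):
                Xr = _expand(g.design, all_counts[r])
                yr = np.repeat(g.outcome, all_counts[r].astype(int))
                for m, tau in enumerate(taus):
                    stack[r, m] = _fit_lp(Xr, yr, float(tau))
            B[k] = stack
        else:
            B[k] = _irls_batch(g.design, g.outcome, taus, all_counts,
                               max_iter=max_iter)

    def make_fit(k, r):
        g = groups[k]
        coef = B[k][r]
        if fits is not None and r == 0:
            return fits[0] if k == "ref" else fits[1]
        obj = np.zeros(taus.size) if r > 0 else np.array(
            [check_loss(g.outcome - g.design @ coef[m], float(t))
             for m, t in enumerate(taus)]
        )
        return QuantileProcessFit(g.label, taus, coef, obj, g.column_names)

    def decompose(r, design_ref, design_cmp):
        agg = aggregate_decompose(
            make_fit("ref", r), make_fit("cmp", r), design_ref, design_cmp, report
        )
        det = detailed_decompose(
            make_fit("ref", r), make_fit("cmp", r), design_ref, design_cmp, agg
        )
        out = {key: getattr(agg, key) for key in _AGG_KEYS}
        out["covariates_detail"] = det.covariates_detail
        out["coefficients_detail"] = det.coefficients_detail
        return out, det

    point, point_det = decompose(0, reference.design, comparison.design)
    names = list(reference.column_names)

    reps_used = int(ok.sum())
    if reps == 0 or reps_used == 0:
        return BootstrapResult(
            reps=0, seed=spec.seed, ci_level=spec.ci_level, report_taus=report,
            point=point, lower=None, upper=None, draws={},
            n_failed=n_failed, column_names=names,
        )

    draws = {key: np.empty((reps_used,) + np.shape(point[key]))
             for key in point}
    kept = np.flatnonzero(ok)
    for i, r in enumerate(kept):
        dref = _expand(reference.design, counts["ref"][r])
        dcmp = _expand(comparison.design, counts["cmp"][r])
        rep, _ = decompose(i + 1, dref, dcmp)
        for key in draws:
            draws[key][i] = rep[key]
        if (i + 1) % 10 == 0:
            logger.info("bootstrap replicate %d/%d", i + 1, reps_used)

    alpha = (1.0 - spec.ci_level) / 2.0
    lower = {k: np.quantile(v, alpha, axis=0) for k, v in draws.items()}
    upper = {k: np.quantile(v, 1.0 - alpha, axis=0) for k, v in draws.items()}
    return BootstrapResult(
        reps=reps, seed=spec.seed, ci_level=spec.ci_level, report_taus=report,
        point=point, lower=lower, upper=upper, draws=draws,
        n_failed=n_failed, column_names=names,
    )
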