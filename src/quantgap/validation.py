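"""Monte-Carlo validation studies for the decomposition pipeline.

These are the package's own calibration experiments: parameter recovery of
the quantile process on location-scale data, null behaviour of the two
decomposition parts, and frequentist coverage of the bootstrap interval
for the median gap.  They are used by the test suite and by the
reproduction script, with problem sizes chosen so each study runs in
minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .bootstrap import bootstrap_decomposition
from .decompose import aggregate_decompose
from .io import AnalysisSpec
from .regression import fit_group_process
from .simulate import RECOVERY_DGP, generate_group, oracle_decomposition, scenario_pair

__all__ = ["recovery_study", "null_part_study", "coverage_study"]


def recovery_study(ns: Sequence[int] = (500, 2000, 8000), seed: int = 0,
                   taus=None) -> dict:
    """Sup-norm error of the fitted quantile process against the true
    location-scale coefficients ``beta + gamma * Phi^{-1}(tau)``.

    Returns ``{n: sup_error}`` for each sample size.
    """
    taus = np.linspace(0.1, 0.9, 9) if taus is None else np.asarray(taus)
    truth = np.asarray(RECOVERY_DGP.beta) + np.outer(
        norm.ppf(taus), RECOVERY_DGP.gamma
    )
    children = np.random.SeedSequence(seed).spawn(len(ns))
    out = {}
    for n, child in zip(ns, children):
        sample = generate_group(replace(RECOVERY_DGP, n=int(n)), child)
        fit = fit_group_process(sample, taus)
        out[int(n)] = float(np.max(np.abs(fit.coef - truth)))
    return out


def null_part_study(
    scenario: str,
    part: str,
    n_per_group: int = 5000,
    n_datasets: int = 12,
    seed: int = 0,
    taus=None,
    report_taus=(0.1, 0.25, 0.5, 0.75, 0.9),
) -> dict:
    """Behaviour of one decomposition part in a scenario where its truth
    is identically zero.

    Fits ``n_datasets`` independent datasets, takes the first as the
    assessed estimate and the spread across datasets as the Monte-Carlo
    standard error of the estimator.  Returns ``{"estimate": (K,),
    "mc_sd": (K,)}`` arrays over the reported quantiles.
    """
    taus = np.round(np.linspace(0.05, 0.95, 19), 4) if taus is None else taus
    dgp_ref, dgp_cmp = scenario_pair(scenario, n_ref=n_per_group, n_cmp=n_per_group)
    report = np.asarray(report_taus, dtype=float)
    children = np.random.SeedSequence(seed).spawn(2 * n_datasets)
    values = np.empty((n_datasets, report.size))
    for d in range(n_datasets):
        ref = generate_group(dgp_ref, children[2 * d])
        cmp_ = generate_group(dgp_cmp, children[2 * d + 1])
        fr = fit_group_process(ref, taus)
        fc = fit_group_process(cmp_, taus)
        agg = aggregate_decompose(fr, fc, ref.design, cmp_.design, report)
        values[d] = getattr(agg, part)
    return {
        "estimate": values[0],
        "mc_sd": values.std(axis=0, ddof=1),
        "all": values,
        "report_taus": report,
    }


def coverage_study(
    n_datasets: int = 200,
    reps: int = 100,
    seed: int = 0,
    scenario: str = "mixed",
    n_ref: int = 575,
    n_cmp: int = 249,
    taus=None,
    max_iter: int = 80,
    oracle_draws: int = 1_000_000,
) -> dict:
    """Empirical coverage of the 95% percentile interval for the median gap.

    Simulates demonstration-sized datasets from a named scenario, runs the
    full bootstrap pipeline on each, and counts how often the pointwise
    interval for difference(0.5) covers the oracle truth.  The estimation
    grid defaults to 9 equispaced quantiles 0.1..0.9, which reproduces the
    pooled median to well under the sampling noise at these sizes.
    """
    taus = np.round(np.linspace(0.1, 0.9, 9), 4) if taus is None else taus
    dgp_ref, dgp_cmp = scenario_pair(scenario, n_ref=n_ref, n_cmp=n_cmp)
    root = np.random.SeedSequence(seed)
    truth_seed, *children = root.spawn(n_datasets + 1)
    truth = oracle_decomposition(
        dgp_ref, dgp_cmp, (0.5,), draws=oracle_draws, seed=truth_seed, tag=scenario
    )
    target = float(truth.difference[0])

    covered = 0
    for d, child in enumerate(children):
        s1, s2, s3 = child.spawn(3)
        ref = generate_group(dgp_ref, s1)
        cmp_ = generate_group(dgp_cmp, s2)
        spec = AnalysisSpec(
            "y", "g", "reference", "comparison", dgp_ref.column_names[1:],
            tau_grid=taus, report_taus=(0.5,), bootstrap_reps=reps,
            ci_level=0.95, seed=int(s3.generate_state(1)[0] % (2**31)),
        )
        res = bootstrap_decomposition(ref, cmp_, spec, max_iter=max_iter)
        lo = res.lower["difference"][0]
        hi = res.upper["difference"][0]
        covered += int(lo <= target <= hi)
    return {
        "coverage": covered / n_datasets,
        "n_datasets": n_datasets,
        "reps": reps,
        "truth_median_difference": target,
    }
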