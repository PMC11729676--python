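"""Output rendering: tables, density summaries, run manifest, orchestration.

Display tables round half-up to one decimal (the convention of published
decomposition tables); full-precision values always go to a parallel
machine-readable file so no information is lost to display rounding.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .errors import QuantgapError
from .estimator import decompose_gap
from .io import AnalysisSpec, load_dataset
from .regression import write_coefficient_table

logger = logging.getLogger(__name__)

__all__ = [
    "density_summary",
    "write_decomposition_table",
    "write_detailed_table",
    "run_decompose",
    "RunManifest",
    "round_half_up",
]


def round_half_up(x, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 39.55 -> 39.6 at one decimal)."""
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(x, decimals: int = 1) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "undefined"
    return f"{round_half_up(float(x), decimals):.{decimals}f}"


def density_summary(outcomes: dict, grid=None, n_points: int = 256):
    """Gaussian-kernel density of each group's outcome on a shared grid.

    Bandwidth by Scott's plug-in rule (recorded per group).  Returns
    ``(grid, curves, bandwidths)`` where ``curves[label]`` integrates to 1
    on the grid within 1%.
    """
    cleaned = {}
    for label, y in outcomes.items():
        y = np.asarray(y, dtype=float)
        if y.size < 2:
            raise QuantgapError(f"group {label!r}: need at least 2 observations")
        if np.std(y) == 0:
            raise QuantgapError(f"group {label!r}: zero-variance outcome")
        cleaned[label] = y
    if grid is None:
        allv = np.concatenate(list(cleaned.values()))
        span = allv.max() - allv.min()
        grid = np.linspace(allv.min() - 0.2 * span, allv.max() + 0.2 * span, n_points)
    grid = np.asarray(grid, dtype=float)
    curves, bandwidths = {}, {}
    for label, y in cleaned.items():
        kde = stats.gaussian_kde(y, bw_method="scott")
        curves[label] = kde(grid)
        bandwidths[label] = float(np.sqrt(kde.covariance[0, 0]))
    return grid, curves, bandwidths


def write_decomposition_table(agg, boot, path, full_path=None) -> None:
    """Write the per-quantile decomposition table.

    ``path`` gets the one-decimal display table; ``full_path`` (default:
    same name with ``_full.json`` suffix) gets full-precision values that
    round-trip exactly.
    """
    path = Path(path)
    taus = agg.report_taus
    rows = []

    def ci(name, k):
        if boot is None or boot.lower is None:
            return ""
        return f"({_fmt(boot.lower[name][k])}, {_fmt(boot.upper[name][k])})"

    spec_rows = [
        ("predicted_reference", agg.q_reference, None),
        ("predicted_comparison", agg.q_comparison, None),
        ("difference", agg.difference, "difference"),
        ("covariates_part", agg.covariates_part, "covariates_part"),
        ("coefficients_part", agg.coefficients_part, "coefficients_part"),
    ]
    for name, values, ciname in spec_rows:
        row = {"quantity": name}
        for k, tau in enumerate(taus):
            row[f"q{int(round(tau * 100))}"] = _fmt(values[k])
            if ciname:
                row[f"q{int(round(tau * 100))}_ci"] = ci(ciname, k)
        rows.append(row)
    for part in ("covariates_part", "coefficients_part"):
        row = {"quantity": f"{part}_pct"}
        pct = agg.contribution_pct(part)
        for k, tau in enumerate(taus):
            row[f"q{int(round(tau * 100))}"] = _fmt(pct[k])
            row[f"q{int(round(tau * 100))}_ci"] = ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)

    if full_path is None:
        full_path = path.with_name(path.stem + "_full.json")
    payload = {
        "report_taus": [float(t) for t in taus],
        "q_reference": agg.q_reference.tolist(),
        "q_comparison": agg.q_comparison.tolist(),
        "q_counterfactual": agg.q_counterfactual.tolist(),
        "difference": agg.difference.tolist(),
        "covariates_part": agg.covariates_part.tolist(),
        "coefficients_part": agg.coefficients_part.tolist(),
    }
    if boot is not None and boot.lower is not None:
        payload["ci_level"] = boot.ci_level
        payload["lower"] = {k: np.asarray(v).tolist() for k, v in boot.lower.items()}
        payload["upper"] = {k: np.asarray(v).tolist() for k, v in boot.upper.items()}
    Path(full_path).write_text(json.dumps(payload, indent=2))


def write_detailed_table(det, path) -> None:
    det.to_frame().to_csv(path, index=False)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    package_version: str
    seed: int
    started: str
    finished: str = ""
    input_digest: str = ""
    exclusions: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    density_bandwidths: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_decompose(spec: AnalysisSpec, input_path, outdir, plots: bool = False) -> RunManifest:
    """Execute the full pipeline on a data file and write all artifacts.

    Artifacts: the decomposition table (+ full-precision JSON), one
    coefficient table per group, the per-covariate detail table, the
    strategy report (JSON + text) and the run manifest.  On error,
    partially written outputs are removed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=spec.to_dict(),
        package_version=__version__,
        seed=spec.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        input_digest=_sha256(input_path),
    )
    written = []

    def out(name):
        p = outdir / name
        written.append(p)
        return p

    try:
        reference, comparison, log = load_dataset(input_path, spec)
        manifest.exclusions = log.to_dict()
        logger.info("loaded %d + %d rows (reference + comparison)",
                    reference.n, comparison.n)
        dec = decompose_gap(reference, comparison, spec)
        write_decomposition_table(
            dec.aggregate_, dec.bootstrap_,
            out("decomposition_table.csv"), out("decomposition_full.json"),
        )
        for fit, tag in ((dec.reference_fit_, "reference"),
                         (dec.comparison_fit_, "comparison")):
            write_coefficient_table(fit, out(f"coefficients_{tag}.csv"))
        write_detailed_table(dec.detailed_, out("detailed_decomposition.csv"))
        out("strategy_report.json").write_text(dec.strategy_report_.to_json())
        out("strategy_report.txt").write_text(dec.strategy_report_.to_text())

        grid, curves, bw = density_summary(
            {str(reference.label): reference.outcome,
             str(comparison.label): comparison.outcome}
        )
        manifest.density_bandwidths = bw
        dens = pd.DataFrame({"outcome": grid, **{k: v for k, v in curves.items()}})
        dens.to_csv(out("density_summary.csv"), index=False)
        if plots:
            _plot_density(grid, curves, out("density_plot.png"))

        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.outputs = [str(p) for p in written] + [str(outdir / "manifest.json")]
        (outdir / "manifest.json").write_text(manifest.to_json())
        return manifest
    except Exception:
        for p in written:
            try:
                Path(p).unlink(missing_ok=True)
            except OSError:
                pass
        raise


def _plot_density(grid, curves, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, dens in curves.items():
        ax.plot(grid, dens, label=str(label))
    ax.set_xlabel("outcome")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
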