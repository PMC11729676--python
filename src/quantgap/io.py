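"""Data ingestion: tabular input, exclusion rules, group splitting.

The analysis compares exactly two levels of a binary grouping variable
(e.g. low vs. high educational attainment).  Rows are partitioned into a
*reference* (advantaged) sample and a *comparison* (disadvantaged) sample;
all other group levels are dropped with a logged warning.  Missing data are
handled by complete-case deletion only; an optional quantile-trim outlier
rule on the outcome is opt-in, never applied silently.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    ParseError,
)

logger = logging.getLogger(__name__)

DEFAULT_TAU_GRID = tuple(np.round(np.linspace(0.01, 0.99, 99), 10))
DEFAULT_REPORT_TAUS = (0.10, 0.25, 0.50, 0.75, 0.90)

INTERCEPT_NAME = "const"


@dataclass(frozen=True)
class AnalysisSpec:
    """Full configuration of one decomposition analysis.

    Parameters
    ----------
    outcome_name : str
        Column holding the numeric outcome (e.g. energy-adjusted
        fruit/vegetable intake per 1000 kcal).
    group_name : str
        Column holding the group indicator.
    reference_level, comparison_level :
        Group values for the advantaged (coefficients donor) and
        disadvantaged group.  Compared as strings against the column.
    covariate_names : sequence of str
        Ordered covariates; the intercept is always prepended by the
        package and must not be listed here.
    tau_grid : sequence of float
        Strictly increasing estimation grid in (0, 1).  Default: 99
        equispaced points 0.01..0.99.
    report_taus : sequence of float
        Quantiles tabulated in reports; must lie within the grid range.
    bootstrap_reps : int
        Bootstrap replications (default 100).
    ci_level : float
        Pointwise confidence level (default 0.95).
    seed : int
        Root seed for all randomness.
    delimiter : str
        Field delimiter of the input file ("," default, "\\t" selectable).
    outlier_bounds : optional (lo, hi)
        Quantile-trim bounds for the outcome; ``None`` keeps all rows.
    solver : {"irls", "exact"}
        Quantile-regression solver passed down to the fitting layer.
    """

    outcome_name: str
    group_name: str
    reference_level: object
    comparison_level: object
    covariate_names: Sequence[str]
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID
    report_taus: Sequence[float] = DEFAULT_REPORT_TAUS
    bootstrap_reps: int = 100
    ci_level: float = 0.95
    seed: int = 0
    delimiter: str = ","
    outlier_bounds: Optional[tuple] = None
    solver: str = "irls"

    def __post_init__(self):
        taus = np.asarray(self.tau_grid, dtype=float)
        if taus.size and (np.any(taus <= 0) or np.any(taus >= 1)):
            raise ConfigurationError("tau_grid values must lie in the open interval (0, 1)")
        if taus.size > 1 and not np.all(np.diff(taus) > 0):
            raise ConfigurationError("tau_grid must be strictly increasing")
        rep = np.asarray(self.report_taus, dtype=float)
        if taus.size and rep.size and (rep.min() < taus.min() or rep.max() > taus.max()):
            raise ConfigurationError(
                "report_taus must lie within the range of tau_grid "
                f"[{taus.min()}, {taus.max()}]"
            )
        if not self.covariate_names:
            raise ConfigurationError("covariate_names must be non-empty")
        if len(set(self.covariate_names)) != len(list(self.covariate_names)):
            raise ConfigurationError("covariate_names must be distinct")
        if str(self.reference_level) == str(self.comparison_level):
            raise ConfigurationError("reference_level and comparison_level must differ")
        if self.bootstrap_reps < 0:
            raise ConfigurationError("bootstrap_reps must be non-negative")
        if not 0 < self.ci_level < 1:
            raise ConfigurationError("ci_level must lie in (0, 1)")
        if self.outlier_bounds is not None:
            lo, hi = self.outlier_bounds
            if not (0 <= lo < hi <= 1):
                raise ConfigurationError(
                    f"outlier bounds must satisfy 0 <= lo < hi <= 1, got ({lo}, {hi})"
                )
        if self.solver not in ("irls", "exact"):
            raise ConfigurationError(f"unknown solver {self.solver!r}")

    @property
    def design_width(self) -> int:
        return len(list(self.covariate_names)) + 1

    @classmethod
    def from_config(cls, path, **overrides) -> "AnalysisSpec":
        """Build a spec from a flat YAML mapping; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "outlier_bounds" in raw and raw["outlier_bounds"] is not None:
            raw["outlier_bounds"] = tuple(raw["outlier_bounds"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tau_grid"] = [float(t) for t in self.tau_grid]
        d["report_taus"] = [float(t) for t in self.report_taus]
        if d["outlier_bounds"] is not None:
            d["outlier_bounds"] = list(d["outlier_bounds"])
        return d


@dataclass
class GroupSample:
    """Outcome vector and design matrix for one analysis group.

    ``design`` is n x (p+1) with a leading column of ones; ``column_names``
    starts with ``"const"``.
    """

    label: object
    outcome: np.ndarray
    design: np.ndarray
    column_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2 or self.outcome.ndim != 1:
            raise ValueError("design must be 2-D and outcome 1-D")
        if self.design.shape[0] != self.outcome.shape[0]:
            raise ValueError("design and outcome row counts differ")
        if np.isnan(self.outcome).any() or np.isnan(self.design).any():
            raise ValueError(f"group {self.label!r}: missing values in sample")
        if not np.all(self.design[:, 0] == 1.0):
            raise ValueError("first design column must be identically 1")
        if not self.column_names:
            p = self.design.shape[1] - 1
            self.column_names = [INTERCEPT_NAME] + [f"x{j}" for j in range(1, p + 1)]
        n, width = self.design.shape
        if n < width + 1:
            raise InsufficientDataError(
                f"group {self.label!r}: n={n} rows < p+2={width + 1} required"
            )

    @property
    def n(self) -> int:
        return self.outcome.shape[0]

    @property
    def width(self) -> int:
        return self.design.shape[1]


@dataclass
class ExclusionLog:
    """Row accounting for one load: input rows must reconcile exactly."""

    n_input: int
    other_level: int
    per_group: dict  # label -> {"missing_outcome", "missing_covariate", "outlier", "retained"}

    def validate(self) -> None:
        total = self.other_level
        for counts in self.per_group.values():
            total += sum(counts.values())
        if total != self.n_input:
            raise AssertionError(
                f"exclusion log does not reconcile: {total} != {self.n_input}"
            )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "other_level": self.other_level,
            "per_group": {str(k): dict(v) for k, v in self.per_group.items()},
        }


def apply_outlier_rule(outcome, rule=None):
    """Return (kept index array, dropped count) under an outlier rule.

    ``rule`` is ``None``/"none" (keep all) or a pair ``(lo, hi)`` of
    quantile bounds: values inside the closed empirical [lo, hi] quantile
    interval are kept.  Quantiles use the package-wide linear-interpolation
    convention of :func:`numpy.quantile`.
    """
    outcome = np.asarray(outcome, dtype=float)
    idx = np.arange(outcome.shape[0])
    if rule is None or (isinstance(rule, str) and rule == "none"):
        return idx, 0
    lo, hi = rule
    if not (0 <= lo < hi <= 1):
        raise ConfigurationError(
            f"outlier bounds must satisfy 0 <= lo < hi <= 1, got ({lo}, {hi})"
        )
    qlo, qhi = np.quantile(outcome, [lo, hi])
    keep = (outcome >= qlo) & (outcome <= qhi)
    return idx[keep], int((~keep).sum())


def _coerce_numeric(series: pd.Series, col: str) -> pd.Series:
    converted = pd.to_numeric(series, errors="coerce")
    bad = converted.isna() & series.notna()
    # blank strings count as missing, anything else is a parse failure
    if bad.any():
        bad &= series.astype(str).str.strip().ne("")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {series.iloc[row]!r} in column {col!r} at data row {row}"
        )
    return converted


def load_dataset(path, spec: AnalysisSpec):
    """Load a delimited file and split it into two validated group samples.

    Returns ``(reference, comparison, log)`` where the samples are
    :class:`GroupSample` objects (intercept prepended, complete cases only)
    and ``log`` is an :class:`ExclusionLog` reconciling every input row.

    The optional outlier rule is applied to the outcome pooled over both
    analysis groups after complete-case filtering, mirroring a global
    outlier screen applied before stratification.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file {path} does not exist")
    df = pd.read_csv(path, sep=spec.delimiter)
    needed = [spec.outcome_name, spec.group_name, *spec.covariate_names]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigurationError(f"input file lacks required column(s): {missing}")

    numeric_cols = [spec.outcome_name, *spec.covariate_names]
    values = pd.DataFrame({c: _coerce_numeric(df[c], c) for c in numeric_cols})
    gcol = df[spec.group_name].astype(str)

    masks = {
        spec.reference_level: (gcol == str(spec.reference_level)).to_numpy(),
        spec.comparison_level: (gcol == str(spec.comparison_level)).to_numpy(),
    }
    other = int(len(df) - sum(int(m.sum()) for m in masks.values()))
    if other:
        logger.warning(
            "dropping %d row(s) with group levels other than %r/%r",
            other, spec.reference_level, spec.comparison_level,
        )

    stage = {}
    for label, mask in masks.items():
        sub = values.loc[mask]
        miss_out = sub[spec.outcome_name].isna()
        sub1 = sub.loc[~miss_out]
        miss_cov = sub1[list(spec.covariate_names)].isna().any(axis=1)
        sub2 = sub1.loc[~miss_cov]
        stage[label] = {
            "frame": sub2,
            "missing_outcome": int(miss_out.sum()),
            "missing_covariate": int(miss_cov.sum()),
        }

    # global outlier screen on the pooled complete-case outcome
    pooled = pd.concat([stage[k]["frame"][spec.outcome_name] for k in stage])
    if spec.outlier_bounds is not None and len(pooled):
        qlo, qhi = np.quantile(pooled.to_numpy(), spec.outlier_bounds)
    else:
        qlo, qhi = -np.inf, np.inf

    samples, per_group = {}, {}
    names = [INTERCEPT_NAME, *spec.covariate_names]
    for label, info in stage.items():
        frame = info["frame"]
        y = frame[spec.outcome_name].to_numpy(dtype=float)
        keep = (y >= qlo) & (y <= qhi)
        frame = frame.loc[keep]
        y = y[keep]
        X = np.column_stack(
            [np.ones(len(frame))]
            + [frame[c].to_numpy(dtype=float) for c in spec.covariate_names]
        ) if len(frame) else np.empty((0, spec.design_width))
        per_group[label] = {
            "missing_outcome": info["missing_outcome"],
            "missing_covariate": info["missing_covariate"],
            "outlier": int((~keep).sum()),
            "retained": int(len(frame)),
        }
        if len(frame) < spec.design_width + 1:
            raise InsufficientDataError(
                f"group {label!r}: {len(frame)} complete rows < "
                f"p+2={spec.design_width + 1} required"
            )
        samples[label] = GroupSample(label, y, X, column_names=names)

    log = ExclusionLog(n_input=int(len(df)), other_level=other, per_group=per_group)
    log.validate()
    return samples[spec.reference_level], samples[spec.comparison_level], log
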