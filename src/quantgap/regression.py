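"""Linear quantile regression over a grid of probabilities.

The conditional quantile model is ``Q_y(tau | x) = x' beta(tau)``; each
``beta(tau)`` is estimated by minimising the check (pinball) loss

    sum_i rho_tau(y_i - x_i' b),   rho_tau(u) = u * (tau - 1[u < 0]).

Two solvers are provided:

``"irls"`` (default)
    Clipped iteratively-reweighted least squares (the smoothing approach
    also used by statsmodels' QuantReg), implemented batched over an
    arbitrary set of (row-weight vector, tau) problems that share one
    design matrix.  Batching is what makes dense bootstrap grids and the
    Monte-Carlo studies affordable: every bootstrap replicate is just an
    integer row-weighting of the original design.
``"exact"``
    The standard linear-programming formulation solved with
    ``scipy.optimize.linprog(method="highs")``; returns a vertex solution
    satisfying the subgradient conditions exactly.

Both satisfy the contract that matters downstream: achieved loss no worse
than least squares at the same tau, and quantile (subgradient) residual
counts up to solver tolerance.  IRLS iterations are frozen per (weight,
tau) cell as soon as that cell converges, so a cell's trajectory — and
hence its result — is independent of what else is in the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from sklearn.base import BaseEstimator

from .errors import SingularDesignError, SolverError

__all__ = [
    "check_loss",
    "fit_quantile",
    "fit_process",
    "QuantileProcessFit",
    "ProcessQuantileRegressor",
    "write_coefficient_table",
]

# Smoothing floor for IRLS residual weights, relative to the outcome scale.
IRLS_EPS = 1e-6
# Per-cell coefficient-change convergence threshold, relative to outcome scale.
IRLS_TOL = 1e-9
DEFAULT_MAX_ITER = 300


def check_loss(residuals, tau: float) -> float:
    """Check (pinball) loss ``sum_i u_i (tau - 1[u_i < 0])``."""
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def _validate_design(X: np.ndarray, column_names=None) -> None:
    n, p = X.shape
    if n < p:
        raise SingularDesignError(
            f"need at least {p} rows for a {p}-column design, got n={n}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the columns involved in the deficiency via QR pivoting
        names = list(column_names) if column_names is not None else [
            f"col{j}" for j in range(p)
        ]
        r = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [names[j] for j in np.argsort(r)[: p - rank]]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"suspect collinear column(s): {bad}"
        )


def _fit_lp(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Exact LP solution of one quantile-regression problem."""
    n, p = X.shape
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A = sparse.hstack(
        [sparse.csr_matrix(X), sparse.eye(n), -sparse.eye(n)], format="csr"
    )
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise SolverError(
            f"LP quantile fit failed at tau={tau}: {res.message} (status {res.status})"
        )
    return res.x[:p]


def _irls_batch(
    X: np.ndarray,
    y: np.ndarray,
    taus: np.ndarray,
    counts: Optional[np.ndarray] = None,
    max_iter: int = DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Batched clipped-IRLS quantile fits.

    Parameters
    ----------
    counts : (R, n) array or None
        Non-negative row multiplicities, one row per weighting (bootstrap
        replicate).  ``None`` means a single unweighted problem.

    Returns
    -------
    B : (R, M, p) coefficient tensor over weightings x taus.
    """
    n, p = X.shape
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    M = taus.size
    if counts is None:
        counts = np.ones((1, n))
    R = counts.shape[0]
    scale = max(1.0, float(np.max(np.abs(y))) if n else 1.0)
    eps = IRLS_EPS * scale
    tol = IRLS_TOL * scale

    b0, *_ = np.linalg.lstsq(X, y, rcond=None)
    B = np.broadcast_to(b0, (R, M, p)).copy()
    XT = X.T.copy()
    active = np.ones((R, M), dtype=bool)
    tau_w = taus[None, :, None]
    for _ in range(max_iter):
        resid = y[None, None, :] - B @ XT
        w = np.where(resid < 0, 1.0 - tau_w, tau_w)
        np.divide(w, np.maximum(np.abs(resid), eps), out=w)
        w *= counts[:, None, :]
        XtWX = np.einsum("rmn,np,nq->rmpq", w, X, X, optimize=True)
        XtWy = (w * y).reshape(R * M, n) @ X
        try:
            Bn = np.linalg.solve(
                XtWX.reshape(R * M, p, p), XtWy[..., None]
            ).reshape(R, M, p)
        except np.linalg.LinAlgError:
            jitter = 1e-10 * np.trace(XtWX, axis1=-2, axis2=-1)[..., None, None]
            XtWX += jitter * np.eye(p)
            Bn = np.linalg.solve(
                XtWX.reshape(R * M, p, p), XtWy[..., None]
            ).reshape(R, M, p)
        delta = np.max(np.abs(Bn - B), axis=2)
        B[active] = Bn[active]
        active &= delta >= tol
        if not active.any():
            break
    return B


def fit_quantile(
    design,
    outcome,
    tau: float,
    solver: str = "irls",
    max_iter: int = DEFAULT_MAX_ITER,
    column_names=None,
) -> np.ndarray:
    """Fit one linear quantile regression and return the coefficient vector.

    The returned coefficients minimise :func:`check_loss` of the residuals;
    with ``solver="exact"`` they are an LP vertex solution, with
    ``solver="irls"`` they agree with it up to smoothing tolerance.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    _validate_design(X, column_names)
    if solver == "exact":
        return _fit_lp(X, y, tau)
    if solver == "irls":
        return _irls_batch(X, y, np.array([tau]), max_iter=max_iter)[0, 0]
    raise ValueError(f"unknown solver {solver!r}")


@dataclass
class QuantileProcessFit:
    """Fitted coefficient process ``tau -> beta(tau)`` for one group."""

    label: object
    tau_grid: np.ndarray
    coef: np.ndarray  # (M, p+1), column 0 the intercept
    objective: np.ndarray  # achieved check loss per tau
    column_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        self.tau_grid = np.asarray(self.tau_grid, dtype=float)
        self.coef = np.asarray(self.coef, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        if self.coef.shape[0] != self.tau_grid.shape[0]:
            raise ValueError("coef rows must align with tau_grid")
        if self.coef.size and not np.all(np.isfinite(self.coef)):
            raise SolverError(f"non-finite coefficients for group {self.label!r}")
        if self.objective.size and np.any(self.objective < -1e-9):
            raise SolverError("negative check loss is impossible")

    @property
    def width(self) -> int:
        return self.coef.shape[1] if self.coef.ndim == 2 else 0

    def predict(self, design) -> np.ndarray:
        """Prediction surface ``x_i' beta(tau_m)`` of shape (n, M)."""
        X = np.asarray(design, dtype=float)
        if X.shape[1] != self.width:
            raise ValueError(
                f"design width {X.shape[1]} != fitted width {self.width}"
            )
        return X @ self.coef.T


def fit_process(
    design,
    outcome,
    tau_grid,
    label=None,
    solver: str = "irls",
    max_iter: int = DEFAULT_MAX_ITER,
    column_names=None,
) -> QuantileProcessFit:
    """Fit the whole coefficient process over ``tau_grid``.

    Row ``m`` of the result equals ``fit_quantile`` at ``tau_grid[m]`` with
    the same solver settings; an empty grid yields an empty fit.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    taus = np.asarray(tau_grid, dtype=float)
    if taus.size == 0:
        return QuantileProcessFit(
            label, taus, np.empty((0, X.shape[1])), np.empty(0), column_names or []
        )
    if np.any(taus <= 0) or np.any(taus >= 1):
        raise ValueError("all grid values must lie in (0, 1)")
    _validate_design(X, column_names)
    if solver == "exact":
        coefs = np.empty((taus.size, X.shape[1]))
        for m, tau in enumerate(taus):
            try:
                coefs[m] = _fit_lp(X, y, float(tau))
            except SolverError as exc:
                raise SolverError(f"at tau={tau}: {exc}") from exc
    elif solver == "irls":
        coefs = _irls_batch(X, y, taus, max_iter=max_iter)[0]
    else:
        raise ValueError(f"unknown solver {solver!r}")
    obj = np.array(
        [check_loss(y - X @ coefs[m], float(t)) for m, t in enumerate(taus)]
    )
    return QuantileProcessFit(label, taus, coefs, obj, column_names or [])


def fit_group_process(sample, tau_grid, solver="irls", max_iter=DEFAULT_MAX_ITER):
    """Convenience wrapper: fit the process of a :class:`~quantgap.io.GroupSample`."""
    return fit_process(
        sample.design,
        sample.outcome,
        tau_grid,
        label=sample.label,
        solver=solver,
        max_iter=max_iter,
        column_names=sample.column_names,
    )


def quantile_counts(residuals, tau, n=None, zero_tol=1e-6):
    """Subgradient residual counts ``(#{r < 0}, #{r <= 0})`` with a zero band.

    At an optimum, ``#{r < 0} <= n * tau <= #{r <= 0}`` (up to solver
    tolerance); residuals within ``zero_tol`` of 0 count as zero.
    """
    r = np.asarray(residuals, dtype=float)
    neg = int(np.sum(r < -zero_tol))
    nonpos = int(np.sum(r <= zero_tol))
    return neg, nonpos


def write_coefficient_table(fit: QuantileProcessFit, path) -> None:
    """Write one group's coefficient process as a delimited table.

    Columns: tau, one column per coefficient, achieved check loss.
    """
    import pandas as pd

    names = list(fit.column_names) or [f"b{j}" for j in range(fit.width)]
    frame = pd.DataFrame(fit.coef, columns=names)
    frame.insert(0, "tau", fit.tau_grid)
    frame["check_loss"] = fit.objective
    frame.to_csv(path, index=False)


class ProcessQuantileRegressor(BaseEstimator):
    """Scikit-learn estimator for a linear quantile process.

    Parameters
    ----------
    taus : sequence of float
        Estimation grid in (0, 1).
    solver : {"irls", "exact"}
    max_iter : int
        IRLS iteration cap.
    fit_intercept : bool
        Prepend an intercept column (default True).

    Attributes
    ----------
    coef_ : (M, p) slope matrix over the grid.
    intercept_ : (M,) intercepts (zeros when ``fit_intercept=False``).
    taus_ : the fitted grid.
    objective_ : achieved check loss per tau.
    """

    def __init__(self, taus=(0.1, 0.25, 0.5, 0.75, 0.9), solver="irls",
                 max_iter=DEFAULT_MAX_ITER, fit_intercept=True):
        self.taus = taus
        self.solver = solver
        self.max_iter = max_iter
        self.fit_intercept = fit_intercept

    def _build_design(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.fit_intercept:
            return np.column_stack([np.ones(X.shape[0]), X])
        return X

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        D = self._build_design(X)
        if D.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        fit = fit_process(D, y, self.taus, solver=self.solver, max_iter=self.max_iter)
        self.n_features_in_ = D.shape[1] - int(self.fit_intercept)
        self.taus_ = fit.tau_grid
        self.objective_ = fit.objective
        if self.fit_intercept:
            self.intercept_ = fit.coef[:, 0].copy()
            self.coef_ = fit.coef[:, 1:].copy()
        else:
            self.intercept_ = np.zeros(fit.tau_grid.size)
            self.coef_ = fit.coef.copy()
        self.process_fit_ = fit
        return self

    def predict(self, X, tau=None):
        """Predicted conditional quantiles, (n, M) or (n,) for one tau."""
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted yet; call fit first")
        X = np.asarray(X, dtype=float)
        preds = X @ self.coef_.T + self.intercept_[None, :]
        if tau is None:
            return preds
        m = np.flatnonzero(np.isclose(self.taus_, tau))
        if m.size == 0:
            raise ValueError(f"tau={tau} is not on the fitted grid")
        return preds[:, m[0]]
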