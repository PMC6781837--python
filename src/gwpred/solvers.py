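"""Penalized whole-genome regression solvers.

Implements the estimators compared in genome-wide prediction studies:

* OLS — unbiased, valid only for n > p;
* ridge regression — beta = (X'X + lam*I)^-1 X'y, computed in the primal
  when p <= n and through the dual identity beta = X'(XX' + lam*I)^-1 y
  when p > n;
* GBLUP — random-effects ridge on the genomic relationship matrix G = XX',
  predicting genetic values g = G (G + lam*I)^-1 y, with lam = sigma_e^2 /
  sigma_g^2;
* LASSO and adaptive LASSO — cyclic coordinate descent with
  soft-thresholding on the objective

      (1/(2n)) ||y - X beta||^2 + lam * sum_j w_j |beta_j|,

  with w = 1 for the plain LASSO. The 1/(2n) loss scaling keeps lambda
  grids comparable across sample sizes; a penalty written without it maps
  onto this one via lam_internal = lam_unscaled / (2n).

Adaptive-LASSO weights come from marginal marker-phenotype covariances
c_j = |x_j' y| / n. The default is w_j = 1 / (c_j + eps), so strongly
associated markers are shrunk less — the point of the adaptive variant.
The alternative w_j = c_j ("literal" mode) is kept for sensitivity
analysis: it penalizes strong markers hardest.

All solvers assume a standardized design and a centered response; no
intercept is fitted anywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("gwpred")

__all__ = [
    "FitResult",
    "PathResult",
    "LambdaGrid",
    "ErrorVarianceEstimate",
    "fit_ols",
    "estimate_error_variance",
    "fit_ridge",
    "fit_gblup",
    "alasso_weights",
    "fit_lasso",
    "lasso_objective",
    "lambda_grid",
    "fit_path",
]

#: singularity gate for OLS normal equations
MAX_CONDITION_NUMBER = 1e12
#: coordinate-descent defaults
CD_TOL = 1e-7
CD_MAX_SWEEPS = 10_000


@dataclass
class FitResult:
    """One fitted coefficient vector with its penalty and convergence state."""

    beta: np.ndarray
    lam: float
    method: str  # OLS | RR | LASSO | ALASSO | GBLUP
    weights: np.ndarray | None = None
    n_iter: int = 0
    converged: bool = True
    objective: float = np.nan

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.isfinite(self.beta).all():
            raise ValueError("non-finite coefficients in fit result")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta


@dataclass
class LambdaGrid:
    """Strictly decreasing penalty grid, log-spaced from lambda_max down."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1 or np.any(self.values <= 0):
            raise ValueError("lambda grid must be positive")
        if np.any(np.diff(self.values) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")

    @property
    def n_lambda(self) -> int:
        return self.values.size

    @property
    def min_ratio(self) -> float:
        return float(self.values[-1] / self.values[0])


@dataclass
class ErrorVarianceEstimate:
    """Unbiased OLS residual variance RSS / (n - p)."""

    sigma2_e: float
    dof: int

    def __post_init__(self) -> None:
        if self.dof <= 0:
            raise ValueError("residual degrees of freedom must be positive")
        if self.sigma2_e < 0:
            raise ValueError("sigma2_e must be >= 0")


@dataclass
class PathResult:
    """Fits along a penalty grid, optionally annotated with test metrics."""

    method: str
    grid: LambdaGrid
    fits: list[FitResult]
    reports: list = field(default_factory=list)  # filled by evaluation.evaluate_path

    def __post_init__(self) -> None:
        if len(self.fits) != self.grid.n_lambda:
            raise ValueError("one fit per grid value required")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Prediction matrix, one column per lambda."""
        B = np.column_stack([f.beta for f in self.fits])
        return X @ B


# ---------------------------------------------------------------------------
# OLS

def fit_ols(X: np.ndarray, y: np.ndarray) -> FitResult:
    """Ordinary least squares via the pseudoinverse (QR-free, SVD-backed).

    Requires n > p and a well-conditioned X'X; high-dimensional data must go
    through the regularized solvers instead.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p > n:
        raise ValueError(
            f"OLS needs n >= p (got n={n}, p={p}); use ridge or the LASSO "
            "for high-dimensional designs"
        )
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] == 0 or (sv[0] / sv[-1]) ** 2 > MAX_CONDITION_NUMBER:
        raise ValueError(
            "X'X is singular or ill-conditioned; use a regularized method"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return FitResult(beta=beta, lam=0.0, method="OLS", objective=rss)


def estimate_error_variance(
    fit: FitResult, X: np.ndarray, y: np.ndarray
) -> ErrorVarianceEstimate:
    """OLS error variance sigma_e^2 = RSS / (n - p)."""
    if fit.method != "OLS":
        raise ValueError("error variance is only unbiased for an OLS fit")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p for residual degrees of freedom (n={n}, p={p})")
    rss = float(np.sum((y - X @ fit.beta) ** 2))
    return ErrorVarianceEstimate(sigma2_e=rss / (n - p), dof=n - p)


# ---------------------------------------------------------------------------
# Ridge / GBLUP

def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> FitResult:
    """Ridge estimator beta = (X'X + lam*I_p)^-1 X'y.

    For p > n the dual identity beta = X'(XX' + lam*I_n)^-1 y is used; both
    routes solve the same normal equations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n, p = X.shape
    if lam == 0:
        return FitResult(beta=fit_ols(X, y).beta, lam=0.0, method="RR")
    if p <= n:
        A = X.T @ X + lam * np.eye(p)
        beta = np.linalg.solve(A, X.T @ y)
    else:
        K = X @ X.T + lam * np.eye(n)
        beta = X.T @ np.linalg.solve(K, y)
    obj = float(np.sum((y - X @ beta) ** 2) + lam * np.sum(beta**2))
    return FitResult(beta=beta, lam=float(lam), method="RR", objective=obj)


def fit_gblup(Gmat: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Predicted genetic values g = G (G + lam*I_n)^-1 y.

    With G = XX' this equals the ridge predictions X beta(lam); lam plays the
    role of the variance ratio sigma_e^2 / sigma_g^2 of random-effects ridge.
    """
    Gmat = np.asarray(Gmat, dtype=float)
    y = np.asarray(y, dtype=float)
    if Gmat.ndim != 2 or Gmat.shape[0] != Gmat.shape[1]:
        raise ValueError("Gmat must be square")
    if not np.allclose(Gmat, Gmat.T, atol=1e-10):
        raise ValueError("Gmat must be symmetric (genomic relationship matrix)")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    n = Gmat.shape[0]
    return Gmat @ np.linalg.solve(Gmat + lam * np.eye(n), y)


# ---------------------------------------------------------------------------
# Adaptive-LASSO weights

def alasso_weights(
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "inverse",
    eps: float | None = None,
) -> np.ndarray:
    """Penalty weights from marginal covariances c_j = |x_j' y| / n.

    mode="inverse" (default): w_j = 1/(c_j + eps) — markers with strong
    marginal association are penalized less. mode="literal": w_j = c_j + eps,
    the covariance itself used as the weight.
    """
    if mode not in ("inverse", "literal"):
        raise ValueError(f"unknown weight mode {mode!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    c = np.abs(X.T @ y) / n
    if eps is None:
        cmax = float(c.max())
        eps = 1e-8 * cmax if cmax > 0 else 1e-8
    if mode == "inverse":
        w = 1.0 / (c + eps)
    else:
        w = c + eps
    if not (np.isfinite(w).all() and (w > 0).all()):
        raise ValueError("weights must be finite and positive")
    return w


# ---------------------------------------------------------------------------
# Coordinate descent (LASSO / adaptive LASSO)

def _cd_kernel_py(X, y, lam, w, beta, tol, max_sweeps):
    n, p = X.shape
    r = y - X @ beta
    xtx_n = np.empty(p)
    for j in range(p):
        xtx_n[j] = np.dot(X[:, j], X[:, j]) / n
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            if xtx_n[j] == 0.0:
                continue
            bj = beta[j]
            z = X[:, j] @ r / n + xtx_n[j] * bj
            t = lam * w[j]
            if z > t:
                bn = (z - t) / xtx_n[j]
            elif z < -t:
                bn = (z + t) / xtx_n[j]
            else:
                bn = 0.0
            d = bn - bj
            if d != 0.0:
                r -= X[:, j] * d
                beta[j] = bn
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            return sweep + 1, True
    return max_sweeps, False


try:  # numba gives ~100x on the inner loop; the pure-Python path is identical
    from numba import njit

    _cd_kernel = njit(cache=True)(_cd_kernel_py)
except ImportError:  # pragma: no cover
    _cd_kernel = _cd_kernel_py


def lasso_objective(
    X: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    lam: float,
    weights: np.ndarray | None = None,
) -> float:
    """(1/(2n)) ||y - X beta||^2 + lam * sum_j w_j |beta_j|."""
    n = X.shape[0]
    w = np.ones(X.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    return float(
        np.sum((y - X @ beta) ** 2) / (2 * n) + lam * np.sum(w * np.abs(beta))
    )


def fit_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    weights: np.ndarray | None = None,
    tol: float = CD_TOL,
    max_sweeps: int = CD_MAX_SWEEPS,
    beta0: np.ndarray | None = None,
) -> FitResult:
    """LASSO / adaptive LASSO by cyclic coordinate descent.

    Minimizes (1/(2n))||y - X beta||^2 + lam * sum_j w_j |beta_j| with the
    soft-thresholding update

        beta_j <- S(x_j' r_(-j) / n, lam * w_j) / (x_j' x_j / n).

    Convergence is declared when the largest coefficient change in a full
    sweep drops below ``tol``; exceeding ``max_sweeps`` warns and returns
    ``converged=False``. ``beta0`` enables warm starts along a path.
    """
    X = np.asfortranarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    p = X.shape[1]
    method = "LASSO"
    if weights is None:
        w = np.ones(p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (p,):
            raise ValueError("weights must have one entry per marker")
        if np.any(w <= 0) or not np.isfinite(w).all():
            raise ValueError("weights must be finite and strictly positive")
        method = "ALASSO"
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    n_iter, converged = _cd_kernel(X, y, float(lam), w, beta, float(tol), int(max_sweeps))
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_sweeps} sweeps "
            f"(lam={lam:g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return FitResult(
        beta=beta,
        lam=float(lam),
        method=method,
        weights=None if weights is None else w,
        n_iter=int(n_iter),
        converged=bool(converged),
        objective=lasso_objective(X, y, beta, lam, weights),
    )


def lambda_max(X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Smallest penalty at which the LASSO solution is exactly zero:
    lam_max = max_j |x_j' y| / (n * w_j)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(p) if weights is None else np.asarray(weights, dtype=float)
    vals = np.abs(X.T @ y) / (n * w)
    lm = float(vals.max())
    if lm == 0:
        raise ValueError("all marginal covariances are zero — no signal to fit")
    return lm


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    n_lambda: int = 100,
    min_ratio: float | None = None,
) -> LambdaGrid:
    """Log-spaced grid from lambda_max down to lambda_max * min_ratio.

    ``min_ratio`` defaults to 0.01 for p > n designs and 1e-4 otherwise,
    mirroring common path-solver practice.
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    n, p = np.asarray(X).shape
    if min_ratio is None:
        min_ratio = 0.01 if p > n else 1e-4
    if not 0 < min_ratio < 1:
        raise ValueError("min_ratio must be in (0, 1)")
    lm = lambda_max(X, y, weights)
    values = np.geomspace(lm, lm * min_ratio, n_lambda)
    return LambdaGrid(values=values)


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    grid: LambdaGrid,
    weights: np.ndarray | None = None,
    tol: float = CD_TOL,
    max_sweeps: int = CD_MAX_SWEEPS,
) -> PathResult:
    """Fit one model per grid value, warm-starting coordinate descent.

    For ridge the grid value is mapped onto the matrix-scale penalty
    n * lam, which is the exact minimizer of the same 1/(2n)-scaled
    objective with an l2 penalty (lam/2)||beta||^2 — so LASSO and ridge
    paths live on a common lambda scale.
    """
    if method not in ("RR", "LASSO", "ALASSO"):
        raise ValueError(f"unknown path method {method!r}")
    X = np.asfortranarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    fits: list[FitResult] = []
    if method == "RR":
        for lam in grid.values:
            f = fit_ridge(X, y, n * lam)
            f.lam = float(lam)  # record on the grid scale
            fits.append(f)
    else:
        if method == "ALASSO" and weights is None:
            weights = alasso_weights(X, y)
        if method == "LASSO":
            weights = None
        beta = None
        for lam in grid.values:
            f = fit_lasso(
                X, y, lam, weights=weights, tol=tol, max_sweeps=max_sweeps, beta0=beta
            )
            f.method = method
            beta = f.beta
            fits.append(f)
    logger.info("fitted %s path over %d lambda values", method, grid.n_lambda)
    return PathResult(method=method, grid=grid, fits=fits)
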