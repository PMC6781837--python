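"""Model-evaluation statistics for hold-out genomic prediction.

Three statistics compete in practice for picking the "best" model on a test
set, and they are not interchangeable:

* test MSE — mean((y - yhat)^2), the honest prediction loss;
* r^2 — the squared Pearson correlation COV[y, yhat]^2 / (VAR[y] VAR[yhat]).
  It is invariant to affine maps of the predictions (a*yhat + b scores the
  same as yhat), so a model whose predictions are systematically shrunk or
  inflated loses nothing under r^2 while its MSE deteriorates;
* R^2 — the coefficient of determination 1 - RSS/TSS on the test set. For a
  fixed test vector y this is a strictly decreasing function of MSE, so
  minimizing MSE and maximizing R^2 always select the same penalty on one
  path; r^2 need not.

``decompose`` reports all of them plus the COV/VAR pieces of r^2, which is
how the affine blind spot of r^2 is diagnosed: regularization shrinks
VAR[yhat] while VAR[y] is fixed.

Moment convention: population (divide-by-n) variances and covariances. r^2
itself is invariant to that choice; the COV/VAR cells are not, so the table
writer can emit both conventions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .solvers import ErrorVarianceEstimate, PathResult

logger = logging.getLogger("gwpred")

__all__ = [
    "EvaluationReport",
    "ModelSelection",
    "RankingTable",
    "mse",
    "r2_pearson",
    "r2_determination",
    "decompose",
    "evaluate_path",
    "ridge_cp_criterion",
    "select_model",
    "rank_individuals",
    "rank_agreement",
    "write_table1",
    "read_table1",
    "write_table2",
    "read_table2",
]

CRITERIA = ("min_mse", "max_r2", "max_R2", "cp_variant")


def _check_pair(y, yhat, min_len=1):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"y and yhat must be 1-D of equal length, got {y.shape} vs {yhat.shape}")
    if y.size < min_len:
        raise ValueError(f"need at least {min_len} observations")
    return y, yhat


def mse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean squared prediction error (1/n) sum (y_i - yhat_i)^2."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean((y - yhat) ** 2))


def r2_pearson(y: np.ndarray, yhat: np.ndarray) -> float:
    """Squared Pearson correlation COV[y,yhat]^2 / (VAR[y] VAR[yhat]).

    A constant predictor has no predictive correlation; that degenerate case
    returns 0 with a warning rather than NaN.
    """
    y, yhat = _check_pair(y, yhat, min_len=2)
    vy = float(np.var(y))
    if vy == 0:
        raise ValueError("var(y) is zero — r^2 undefined")
    vh = float(np.var(yhat))
    if vh == 0:
        warnings.warn(
            "constant predictions: r^2 defined as 0", RuntimeWarning, stacklevel=2
        )
        return 0.0
    c = float(np.mean((y - y.mean()) * (yhat - yhat.mean())))
    return c * c / (vy * vh)


def r2_determination(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - sum(y-yhat)^2 / sum(y-ybar)^2.

    ``ybar`` is the mean of the supplied test responses. Can be negative
    when the model predicts worse than the test mean.
    """
    y, yhat = _check_pair(y, yhat, min_len=2)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("constant y — R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / tss


@dataclass
class EvaluationReport:
    """All competing test-set statistics for one model on one split."""

    mse: float
    r2_pearson: float
    r2_determination: float
    cov_y_yhat: float
    var_y: float
    var_yhat: float
    n_test: int

    def as_dict(self) -> dict:
        return {
            "MSE": self.mse,
            "r2": self.r2_pearson,
            "R2": self.r2_determination,
            "COV": self.cov_y_yhat,
            "VAR_yhat": self.var_yhat,
            "VAR_y": self.var_y,
        }


def decompose(y: np.ndarray, yhat: np.ndarray) -> EvaluationReport:
    """Full report: MSE, r^2, R^2 and the COV/VAR pieces of r^2."""
    y, yhat = _check_pair(y, yhat, min_len=2)
    vy = float(np.var(y))
    vh = float(np.var(yhat))
    c = float(np.mean((y - y.mean()) * (yhat - yhat.mean())))
    return EvaluationReport(
        mse=mse(y, yhat),
        r2_pearson=r2_pearson(y, yhat),
        r2_determination=r2_determination(y, yhat),
        cov_y_yhat=c,
        var_y=vy,
        var_yhat=vh,
        n_test=int(y.size),
    )


def evaluate_path(
    path: PathResult, X_test: np.ndarray, y_test: np.ndarray
) -> PathResult:
    """Attach one EvaluationReport per lambda to a fitted path (in place)."""
    Yhat = path.predict(np.asarray(X_test, dtype=float))
    with warnings.catch_warnings():
        # the all-zero fit at lambda_max legitimately predicts a constant
        warnings.simplefilter("ignore", RuntimeWarning)
        path.reports = [decompose(y_test, Yhat[:, k]) for k in range(Yhat.shape[1])]
    return path


# ---------------------------------------------------------------------------
# Ridge tuning without a test set: Cp-style unbiased risk estimate

def ridge_df(X: np.ndarray, lam: float) -> float:
    """Effective degrees of freedom tr[X'X (X'X + lam*I)^-1] via eigenvalues."""
    d = np.linalg.eigvalsh(X.T @ X)
    d = np.clip(d, 0.0, None)
    return float(np.sum(d / (d + lam)))


def ridge_cp_criterion(
    X_train: np.ndarray,
    y_train: np.ndarray,
    lam: float,
    sigma2_e: ErrorVarianceEstimate,
) -> float:
    """Unbiased-risk (Cp-variant) criterion RSS(lam) - n*s2 + 2*s2*df(lam).

    ``lam`` is on the matrix scale of (X'X + lam*I); ``df`` is the ridge
    trace tr[X'X (X'X + lam*I)^-1]. Requires an external unbiased error
    variance, e.g. from an OLS sub-problem with n > p.
    """
    from .solvers import fit_ridge

    if sigma2_e is None:
        raise ValueError("ridge Cp criterion needs an error-variance estimate")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    n = X_train.shape[0]
    beta = fit_ridge(X_train, y_train, lam).beta
    rss = float(np.sum((y_train - X_train @ beta) ** 2))
    s2 = sigma2_e.sigma2_e
    return rss - n * s2 + 2.0 * s2 * ridge_df(X_train, lam)


# ---------------------------------------------------------------------------
# Model selection along a path

@dataclass
class ModelSelection:
    criterion: str
    best_lambda: float
    best_index: int
    best_report: EvaluationReport


def select_model(
    path: PathResult,
    criterion: str,
    X_train: np.ndarray | None = None,
    y_train: np.ndarray | None = None,
    sigma2_e: ErrorVarianceEstimate | None = None,
) -> ModelSelection:
    """Pick the extremal grid point under a criterion; ties go to larger lam.

    ``min_mse``/``max_r2``/``max_R2`` need ``evaluate_path`` to have been run.
    ``cp_variant`` (ridge only) instead needs the training data and an error
    variance; the report at the chosen lambda is still returned if present.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    if criterion == "cp_variant":
        if path.method != "RR":
            raise ValueError("cp_variant applies to ridge paths only")
        n = X_train.shape[0]
        scores = np.array(
            [
                ridge_cp_criterion(X_train, y_train, n * lam, sigma2_e)
                for lam in path.grid.values
            ]
        )
    else:
        if not path.reports:
            raise ValueError("path has no test reports; run evaluate_path first")
        key = {"min_mse": "mse", "max_r2": "r2_pearson", "max_R2": "r2_determination"}[
            criterion
        ]
        sign = 1.0 if criterion == "min_mse" else -1.0
        scores = sign * np.array([getattr(r, key) for r in path.reports])
    # grid is lambda-descending, so the first argmin is the largest lambda
    best = int(np.argmin(scores))
    report = path.reports[best] if path.reports else None
    return ModelSelection(
        criterion=criterion,
        best_lambda=float(path.grid.values[best]),
        best_index=best,
        best_report=report,
    )


# ---------------------------------------------------------------------------
# Individual ranking

@dataclass
class RankingTable:
    """Top individuals by predicted value, descending; ties by id."""

    top_ids: list[str]
    predicted_values: np.ndarray

    def __post_init__(self) -> None:
        self.predicted_values = np.asarray(self.predicted_values, dtype=float)
        if len(self.top_ids) != self.predicted_values.size:
            raise ValueError("ids and values must have equal length")
        if len(set(self.top_ids)) != len(self.top_ids):
            raise ValueError("duplicated ids in ranking")
        if np.any(np.diff(self.predicted_values) > 0):
            raise ValueError("predicted_values must be non-increasing")


def rank_individuals(yhat: np.ndarray, ids, k: int) -> RankingTable:
    """Top-k individuals by prediction, descending; ties broken by id."""
    yhat = np.asarray(yhat, dtype=float)
    ids = [str(i) for i in ids]
    if len(ids) != yhat.size:
        raise ValueError("ids and predictions must have equal length")
    if not 1 <= k <= yhat.size:
        raise ValueError(f"k must be in [1, {yhat.size}], got {k}")
    order = sorted(range(yhat.size), key=lambda i: (-yhat[i], ids[i]))[:k]
    return RankingTable(
        top_ids=[ids[i] for i in order], predicted_values=yhat[order]
    )


def rank_agreement(r1, r2, k: int | None = None) -> dict:
    """Spearman rho, Kendall tau and top-k overlap between two orderings.

    Inputs are full orderings (sequences of ids, best first) or
    RankingTables over the same id universe. Rank correlations are computed
    on the shared universe; the overlap fraction uses the top ``k`` ids
    (default: the full table length).
    """
    ids1 = list(r1.top_ids) if isinstance(r1, RankingTable) else [str(i) for i in r1]
    ids2 = list(r2.top_ids) if isinstance(r2, RankingTable) else [str(i) for i in r2]
    if set(ids1) != set(ids2):
        raise ValueError("orderings must cover the same id universe")
    pos2 = {x: i for i, x in enumerate(ids2)}
    ranks1 = np.arange(len(ids1))
    ranks2 = np.array([pos2[x] for x in ids1])
    if len(ids1) < 2:
        rho = tau = 1.0
    else:
        rho = float(stats.spearmanr(ranks1, ranks2).statistic)
        tau = float(stats.kendalltau(ranks1, ranks2).statistic)
    kk = k if k is not None else len(ids1)
    overlap = len(set(ids1[:kk]) & set(ids2[:kk])) / kk
    return {"spearman": rho, "kendall": tau, "topk_overlap": overlap}


# ---------------------------------------------------------------------------
# Report writers (Table-1 / Table-2 style CSVs)

def write_table1(
    reports: dict[str, EvaluationReport],
    path: str | Path,
    header_lines: list[str] | None = None,
    moment_convention: str = "population",
) -> None:
    """Method x metric grid: MSE, r^2, R^2, COV[y,yhat], VAR[yhat], VAR[y].

    ``moment_convention`` "population" divides second moments by n; "sample"
    rescales COV/VAR by n/(n-1). r^2, R^2 and MSE are unaffected.
    """
    if moment_convention not in ("population", "sample"):
        raise ValueError("moment_convention must be 'population' or 'sample'")
    rows = []
    for method, rep in reports.items():
        d = rep.as_dict()
        if moment_convention == "sample":
            f = rep.n_test / (rep.n_test - 1)
            for kk in ("COV", "VAR_yhat", "VAR_y"):
                d[kk] *= f
        rows.append({"method": method, **d})
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for ln in header_lines or []:
            fh.write(f"# {ln}\n")
        df.to_csv(fh, index=False)


def read_table1(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_table2(
    rankings: dict[str, RankingTable],
    path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    """Method/criterion x rank grid of top individual ids."""
    rows = [
        {"selection": name, **{f"rank{i+1}": x for i, x in enumerate(t.top_ids)}}
        for name, t in rankings.items()
    ]
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for ln in header_lines or []:
            fh.write(f"# {ln}\n")
        df.to_csv(fh, index=False)


def read_table2(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype=str)
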