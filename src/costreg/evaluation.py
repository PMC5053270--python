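"""Forecast evaluation: bias/accuracy/goodness-of-fit metrics, the Pearson
misspecification test, decile profiles of predicted cost, and response
surfaces of metrics against inverse sample size.

Metric conventions: MPE = mean(y - yhat) measures aggregate bias (errors
cancel), MAPE = mean|y - yhat| measures individual accuracy, RMSE =
sqrt(mean (y - yhat)^2) penalizes large errors disproportionately; ADMPE,
computed across replications, is |MPE_r - mean_r MPE| and measures the
variability of the bias.  All divisors are the number of evaluated
observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricRecord",
    "PearsonTestResult",
    "DecileProfile",
    "ResponseSurface",
    "compute_metrics",
    "add_admpe",
    "pearson_test",
    "decile_profile",
    "fit_response_surface",
]


@dataclass
class MetricRecord:
    model: str
    sample_size: int
    replication: int
    mpe: float
    mape: float
    rmse: float
    n_eval: int
    admpe: float = np.nan  # filled in across replications

    def __post_init__(self):
        for v in (self.mpe, self.mape, self.rmse):
            if not np.isfinite(v):
                raise ValueError("metrics must be finite")
        if not (self.rmse >= self.mape - 1e-9 and self.mape >= abs(self.mpe) - 1e-9):
            raise ValueError("power-mean ordering rmse >= mape >= |mpe| violated")


@dataclass
class PearsonTestResult:
    slope: float
    p_value: float
    reject_5pct: bool
    applicable: bool = True


@dataclass
class DecileProfile:
    model: str
    decile: int  # 1..10 of predicted cost
    mpe: float
    mape: float
    n: int


@dataclass
class ResponseSurface:
    model: str
    metric: str
    alpha: float  # large-sample asymptote of the metric
    beta_inv_n: float  # slope on 1 / Ns
    alpha_se: float
    alpha_p_value: float  # H0: alpha = 0, an indication of consistency
    beta_se: float


def compute_metrics(y: np.ndarray, yhat: np.ndarray, model: str = "",
                    sample_size: int = 0, replication: int = 0) -> MetricRecord:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) == 0:
        raise ValueError("actuals and predictions must be equal-length vectors")
    err = y - yhat
    return MetricRecord(
        model=model,
        sample_size=sample_size,
        replication=replication,
        mpe=float(err.mean()),
        mape=float(np.abs(err).mean()),
        rmse=float(np.sqrt(np.mean(err**2))),
        n_eval=len(y),
    )


def add_admpe(records: list[MetricRecord]) -> list[MetricRecord]:
    """Fill each record's ADMPE: absolute deviation of its MPE from the
    mean MPE of its (model, sample size) cell."""
    df = pd.DataFrame([(r.model, r.sample_size, r.mpe) for r in records],
                      columns=["model", "Ns", "mpe"])
    cell_mean = df.groupby(["model", "Ns"])["mpe"].transform("mean")
    for r, m in zip(records, cell_mean):
        r.admpe = abs(r.mpe - m)
    return records


def pearson_test(y: np.ndarray, yhat: np.ndarray, level: float = 0.05) -> PearsonTestResult:
    """Regress raw-scale residuals on predicted costs; a significant slope
    is evidence of a detectable linear misspecification.  Undefined for
    constant predictions (e.g. OLS residuals are orthogonal to fitted
    values by construction, so the test cannot reject for in-sample OLS)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least three observations")
    if np.ptp(yhat) == 0.0:
        return PearsonTestResult(np.nan, np.nan, False, applicable=False)
    resid = y - yhat
    xc = yhat - yhat.mean()
    slope = float(xc @ resid / (xc @ xc))
    intercept = resid.mean() - slope * yhat.mean()
    u = resid - intercept - slope * yhat
    s2 = float(u @ u) / (n - 2)
    se = np.sqrt(s2 / (xc @ xc))
    if se == 0.0:
        return PearsonTestResult(slope, 1.0, False)
    t = slope / se
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return PearsonTestResult(slope, p, p < level)


def decile_profile(y: np.ndarray, yhat: np.ndarray, model: str = "") -> list[DecileProfile]:
    """Rank observations by predicted cost, split into ten near-equal
    groups (stable order breaks ties deterministically), report per-group
    MPE and MAPE."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least ten observations for deciles")
    order = np.argsort(yhat, kind="stable")
    groups = np.array_split(order, 10)
    out = []
    for d, idx in enumerate(groups, start=1):
        err = y[idx] - yhat[idx]
        out.append(DecileProfile(model=model, decile=d, mpe=float(err.mean()),
                                 mape=float(np.abs(err).mean()), n=len(idx)))
    return out


def fit_response_surface(records: list[MetricRecord], model: str,
                         metric: str) -> ResponseSurface:
    """OLS of the metric (MPE) or its log (MAPE/RMSE/ADMPE) on 1/Ns.  The
    intercept alpha is the metric's large-sample asymptote; for MPE,
    alpha not significantly different from zero indicates a consistent
    estimator."""
    metric = metric.upper()
    getter = {"MPE": lambda r: r.mpe, "MAPE": lambda r: r.mape,
              "RMSE": lambda r: r.rmse, "ADMPE": lambda r: r.admpe}
    if metric not in getter:
        raise ValueError(f"unknown metric {metric!r}")
    rows = [(r.sample_size, getter[metric](r)) for r in records if r.model == model]
    if not rows:
        raise ValueError(f"no records for model {model!r}")
    ns = np.array([r[0] for r in rows], dtype=float)
    vals = np.array([r[1] for r in rows], dtype=float)
    if len(np.unique(ns)) < 2:
        raise ValueError("need at least two distinct sample sizes")
    if metric != "MPE":
        if np.any(vals <= 0):
            raise ValueError(f"log specification needs positive {metric} values")
        vals = np.log(vals)
    Z = np.column_stack([np.ones_like(ns), 1.0 / ns])
    coef, *_ = np.linalg.lstsq(Z, vals, rcond=None)
    resid = vals - Z @ coef
    dof = max(len(vals) - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(Z.T @ Z)
    alpha_se = float(np.sqrt(cov[0, 0]))
    beta_se = float(np.sqrt(cov[1, 1]))
    if alpha_se > 0:
        p = float(2.0 * stats.t.sf(abs(coef[0] / alpha_se), df=dof))
    else:
        p = 0.0 if coef[0] != 0 else 1.0
    return ResponseSurface(model=model, metric=metric, alpha=float(coef[0]),
                           beta_inv_n=float(coef[1]), alpha_se=alpha_se,
                           alpha_p_value=p, beta_se=beta_se)
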