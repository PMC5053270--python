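"""Conditional density approximation estimation of mean costs.

The cost range observed in the estimation sample is partitioned into Q
intervals (quantile-based, so every interval is populated even at skewness
above 10).  Interval membership is modelled either by a multinomial logit
(one coefficient vector per interval, the first normalized to zero) or an
ordered logit (a single coefficient vector plus Q-1 increasing thresholds).
The conditional mean is the probability-weighted sum of the fixed,
estimation-sample bin means:

    E[y|X] = sum_j p_j(X) ybar_j,

so predictions are bounded by the extreme bin means — a structural
difference from parametric models, which can extrapolate beyond the
observed cost range.  The interval probabilities decompose exactly into
discrete hazards lambda(j|X) = p_j / (1 - sum_{l<j} p_l), the discrete
analogue of a hazard-rate factorization of the density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .datasets import CostDataset

__all__ = [
    "IntervalPartition",
    "CDEParams",
    "build_partition",
    "assign_intervals",
    "fit_cde",
    "interval_probs",
    "probs_to_hazards",
    "hazards_to_probs",
    "cde_mean",
]


@dataclass
class IntervalPartition:
    Q: int
    boundaries: np.ndarray  # length Q + 1; first = min cost, last = max cost
    bin_means: np.ndarray  # length Q, estimation-sample means
    bin_counts: np.ndarray

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.boundaries) != self.Q + 1 or len(self.bin_means) != self.Q:
            raise ValueError("inconsistent partition sizes")


@dataclass
class CDEParams:
    partition: IntervalPartition
    model: str  # "multinomial" or "ordered"
    mnl_betas: np.ndarray | None = None  # k x Q, first column zero
    ol_psi: np.ndarray | None = None  # Q - 1 increasing thresholds
    ol_beta: np.ndarray | None = None  # coefficients for X without intercept
    converged: bool = True

    def to_dict(self) -> dict:
        out = {
            "model": "CDEM" if self.model == "multinomial" else "CDEO",
            "converged": self.converged,
            "partition": {
                "Q": self.partition.Q,
                "boundaries": list(map(float, self.partition.boundaries)),
                "bin_means": list(map(float, self.partition.bin_means)),
            },
        }
        if self.mnl_betas is not None:
            out["mnl_betas"] = self.mnl_betas.tolist()
        if self.ol_psi is not None:
            out["ol_psi"] = list(map(float, self.ol_psi))
            out["ol_beta"] = list(map(float, self.ol_beta))
        return out


def build_partition(y: np.ndarray, Q: int = 15) -> IntervalPartition:
    """Equal-probability (quantile) partition of the observed cost range.

    Boundary observations belong to the lower interval.  Mass points that
    collapse adjacent quantiles are merged with a warning; the realized
    interval count may then be below Q.
    """
    y = np.asarray(y, dtype=float)
    if Q < 2:
        raise ValueError("need at least two intervals")
    if len(np.unique(y)) < Q:
        raise ValueError(f"only {len(np.unique(y))} distinct costs for Q={Q} intervals")
    qs = np.linspace(0.0, 1.0, Q + 1)
    boundaries = np.quantile(y, qs)
    boundaries[0], boundaries[-1] = y.min(), y.max()
    uniq = np.unique(boundaries)
    if len(uniq) < len(boundaries):
        warnings.warn(
            f"mass points collapsed {len(boundaries) - len(uniq)} quantile boundaries; "
            f"using {len(uniq) - 1} intervals instead of {Q}",
            stacklevel=2,
        )
        boundaries = uniq
    if len(boundaries) < 3:
        raise ValueError("fewer than two intervals survive boundary merging")
    Q_eff = len(boundaries) - 1
    lab = _assign(boundaries, y)
    counts = np.bincount(lab, minlength=Q_eff)
    if np.any(counts == 0):
        raise ValueError("empty interval after partitioning")
    means = np.array([y[lab == j].mean() for j in range(Q_eff)])
    return IntervalPartition(Q=Q_eff, boundaries=boundaries, bin_means=means,
                             bin_counts=counts)


def _assign(boundaries: np.ndarray, y: np.ndarray) -> np.ndarray:
    # ties at an interior boundary go to the lower interval
    lab = np.searchsorted(boundaries[1:-1], y, side="left")
    return np.clip(lab, 0, len(boundaries) - 2)


def assign_intervals(partition: IntervalPartition, y: np.ndarray) -> np.ndarray:
    return _assign(partition.boundaries, np.asarray(y, dtype=float))


def fit_cde(data: CostDataset, partition: IntervalPartition | None = None,
            model: str = "multinomial", Q: int = 15) -> CDEParams:
    """ML fit of the chosen logit model over interval labels; separation or
    singularity is flagged as non-convergence."""
    import statsmodels.api as sm
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    if partition is None:
        partition = build_partition(data.y, Q=Q)
    labels = assign_intervals(partition, data.y)
    Qe = partition.Q
    k = data.X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if model == "multinomial":
                res = sm.MNLogit(labels, data.X).fit(method="lbfgs", maxiter=2000,
                                                     disp=False)
                betas = np.column_stack([np.zeros(k), np.asarray(res.params)])
                ok = bool(res.mle_retvals.get("converged", True))
                return CDEParams(partition=partition, model=model,
                                 mnl_betas=betas, converged=ok)
            if model == "ordered":
                # intercept is absorbed by the thresholds
                res = OrderedModel(labels, data.X[:, 1:], distr="logit").fit(
                    method="bfgs", maxiter=500, disp=False
                )
                k1 = k - 1
                beta = np.asarray(res.params[:k1], dtype=float)
                thresholds = res.model.transform_threshold_params(res.params)[1:-1]
                ok = bool(res.mle_retvals.get("converged", True))
                return CDEParams(partition=partition, model=model,
                                 ol_psi=np.asarray(thresholds, dtype=float),
                                 ol_beta=beta, converged=ok)
            raise ValueError(f"unknown CDE model {model!r}")
    except (np.linalg.LinAlgError, ValueError) as exc:
        if "unknown CDE model" in str(exc):
            raise
        return CDEParams(partition=partition, model=model, converged=False)


def interval_probs(params: CDEParams, X_new: np.ndarray) -> np.ndarray:
    """n x Q matrix of interval-membership probabilities; rows sum to 1."""
    X_new = np.asarray(X_new, dtype=float)
    if params.model == "multinomial":
        eta = X_new @ params.mnl_betas  # n x Q, first column identically 0
        return np.exp(eta - logsumexp(eta, axis=1)[:, None])
    eta = X_new[:, 1:] @ params.ol_beta
    cdf = expit(params.ol_psi[None, :] - eta[:, None])  # n x (Q-1)
    cum = np.concatenate(
        [np.zeros((len(eta), 1)), cdf, np.ones((len(eta), 1))], axis=1
    )
    probs = np.diff(cum, axis=1)
    return np.maximum(probs, 0.0)


def probs_to_hazards(probs: np.ndarray) -> np.ndarray:
    """Discrete hazards lambda_j = p_j / (1 - sum_{l<j} p_l); beyond
    exhausted support the hazard is defined as 1."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    cum_before = np.concatenate(
        [np.zeros((probs.shape[0], 1)), np.cumsum(probs, axis=1)[:, :-1]], axis=1
    )
    denom = 1.0 - cum_before
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(denom > 1e-300, probs / np.maximum(denom, 1e-300), 1.0)
    return np.clip(lam, 0.0, 1.0)


def hazards_to_probs(hazards: np.ndarray) -> np.ndarray:
    """Inverse of :func:`probs_to_hazards`: p_j = lambda_j prod_{l<j}(1 - lambda_l)."""
    lam = np.atleast_2d(np.asarray(hazards, dtype=float))
    surv_before = np.concatenate(
        [np.ones((lam.shape[0], 1)), np.cumprod(1.0 - lam, axis=1)[:, :-1]], axis=1
    )
    return lam * surv_before


def cde_mean(params: CDEParams, X_new: np.ndarray) -> np.ndarray:
    """Probability-weighted sum of estimation-sample bin means (Eq. above);
    bounded by the smallest and largest bin mean."""
    return interval_probs(params, X_new) @ params.partition.bin_means
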