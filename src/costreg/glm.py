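"""Quasi-likelihood GLMs for cost means: log or square-root link, with
variance proportional to the mean (Poisson-type) or the mean squared
(gamma-type).

Only the first two conditional moments are assumed; coefficients solve the
quasi-score equations and are consistent whenever the mean function is
right, whatever the true cost distribution.  Estimation is statsmodels'
IRLS, started from OLS on the link-transformed outcome so the square-root
link's index stays positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datasets import CostDataset

__all__ = ["GLMFit", "fit_glm", "predict_mean"]


@dataclass
class GLMFit:
    link: str  # "log" or "sqrt"
    var_power: int  # 1 (Poisson-type) or 2 (gamma-type)
    beta: np.ndarray
    dispersion: float
    converged: bool
    iterations: int

    @property
    def label(self) -> str:
        return f"GLM{self.link.upper()}{'P' if self.var_power == 1 else 'G'}"

    def to_dict(self) -> dict:
        return {
            "link": self.link,
            "var_power": self.var_power,
            "beta": self.beta.tolist(),
            "dispersion": self.dispersion,
            "converged": self.converged,
        }


def _family(link: str, var_power: int):
    if link == "log":
        sm_link = sm.families.links.Log()
    elif link == "sqrt":
        sm_link = sm.families.links.Sqrt()
    else:
        raise ValueError(f"unknown link {link!r}")
    if var_power == 1:
        return sm.families.Poisson(link=sm_link)
    if var_power == 2:
        # sqrt is a perfectly good quasi-likelihood link for a gamma-type
        # variance even though statsmodels does not list it as canonical
        return sm.families.Gamma(link=sm_link, check_link=False)
    raise ValueError("var_power must be 1 (Poisson-type) or 2 (gamma-type)")


def fit_glm(data: CostDataset, link: str = "log", var_power: int = 2) -> GLMFit:
    """Solve the quasi-score equations sum_i (dmu/db)(y - mu)/V(mu) = 0
    with mu = g^{-1}(Xb) and V(mu) = mu^var_power; dispersion from Pearson
    residuals.  Non-convergence is flagged, not raised."""
    if np.any(data.y <= 0):
        raise ValueError("quasi-GLMs here require strictly positive costs")
    fam = _family(link, var_power)
    z = np.log(data.y) if link == "log" else np.sqrt(data.y)
    start, *_ = np.linalg.lstsq(data.X, z, rcond=None)
    try:
        with warnings.catch_warnings():
            # the Poisson family warns on non-integer y and non-canonical links;
            # both are deliberate for quasi-likelihood use
            warnings.simplefilter("ignore")
            model = sm.GLM(data.y, data.X, family=fam)
            res = model.fit(start_params=start, maxiter=300, tol=1e-8, scale="X2")
        beta = np.asarray(res.params, dtype=float)
        mu = np.asarray(res.fittedvalues, dtype=float)
        ok = (
            bool(res.converged)
            and np.all(np.isfinite(beta))
            and np.all(mu > 0)
            and (link != "sqrt" or np.all(data.X @ beta > 0))
        )
        return GLMFit(
            link=link,
            var_power=var_power,
            beta=beta,
            dispersion=float(res.scale),
            converged=ok,
            iterations=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
        )
    except (np.linalg.LinAlgError, ValueError, FloatingPointError):
        k = data.X.shape[1]
        return GLMFit(link, var_power, np.full(k, np.nan), np.nan, False, 0)


def predict_mean(fit: GLMFit, X_new: np.ndarray) -> np.ndarray:
    """Conditional-mean predictions: exp(Xb) for the log link, (Xb)^2 for
    the square-root link."""
    eta = np.asarray(X_new, dtype=float) @ fit.beta
    return np.exp(eta) if fit.link == "log" else eta**2
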