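"""OLS on levels, logs or square roots of cost, with Duan-type smearing.

A regression of a transformed outcome predicts on the transformed scale;
recovering the conditional mean of cost itself requires a retransformation
correction (the smearing factor).  Under heteroscedasticity the factor
varies with covariates, so it is itself estimated by regressing a
transformed residual on the covariate vector:

- log:  E[y|X] = exp(Xb) * E[exp(e)|X]; the factor regression projects
  exp(residual) on X and the correction multiplies.
- sqrt: E[y|X] = (Xb)^2 + E[e^2|X]; the factor regression projects the
  squared residual on X and the correction adds.
- identity: no retransformation; predictions are Xb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import CostDataset

__all__ = ["TransformOLSFit", "fit_transform_ols", "retransform_predict"]

TRANSFORMS = ("identity", "log", "sqrt")

# clip floors for fitted smearing values: a linear projection of a positive
# quantity can dip negative in the tails
_SMEAR_FLOOR = {"log": 1e-6, "sqrt": 0.0}


@dataclass
class TransformOLSFit:
    transform: str
    beta: np.ndarray
    residuals: np.ndarray
    smearing_model: np.ndarray | None  # aux-regression coefficients, None for identity
    heteroscedastic: bool = True
    smearing_constant: float | None = None  # homoscedastic fallback / option

    def to_dict(self) -> dict:
        return {
            "transform": self.transform,
            "beta": self.beta.tolist(),
            "smearing_model": None if self.smearing_model is None else self.smearing_model.tolist(),
            "heteroscedastic": self.heteroscedastic,
            "smearing_constant": self.smearing_constant,
        }


def _apply_transform(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return y
    if transform == "log":
        return np.log(y)
    if transform == "sqrt":
        return np.sqrt(y)
    raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")


def _ols(X: np.ndarray, z: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(X, z, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix rank {rank} < {X.shape[1]} columns: collinear design"
        )
    return beta


def fit_transform_ols(
    data: CostDataset, transform: str = "log", heteroscedastic: bool = True
) -> TransformOLSFit:
    """OLS of the transformed outcome on X, plus the auxiliary smearing
    regression of the link-transformed residual on the same covariates."""
    if transform in ("log", "sqrt") and np.any(data.y <= 0):
        raise ValueError(f"{transform} transform requires strictly positive costs")
    z = _apply_transform(data.y, transform)
    beta = _ols(data.X, z)
    resid = z - data.X @ beta

    smear_coefs = None
    smear_const = None
    if transform == "log":
        target = np.exp(resid)
    elif transform == "sqrt":
        target = resid**2
    else:
        target = None
    if target is not None:
        smear_const = float(target.mean())
        if heteroscedastic:
            smear_coefs = _ols(data.X, target)
    return TransformOLSFit(
        transform=transform,
        beta=beta,
        residuals=resid,
        smearing_model=smear_coefs,
        heteroscedastic=heteroscedastic,
        smearing_constant=smear_const,
    )


def smearing_factors(fit: TransformOLSFit, X_new: np.ndarray) -> np.ndarray | None:
    """Per-observation smearing corrections on the cost scale (None for the
    identity transform)."""
    if fit.transform == "identity":
        return None
    X_new = np.asarray(X_new, dtype=float)
    if fit.heteroscedastic:
        s = X_new @ fit.smearing_model
    else:
        s = np.full(X_new.shape[0], fit.smearing_constant)
    if not np.all(np.isfinite(s)):
        raise FloatingPointError("non-finite smearing fitted values")
    return np.maximum(s, _SMEAR_FLOOR[fit.transform])


def retransform_predict(fit: TransformOLSFit, X_new: np.ndarray) -> np.ndarray:
    """Mean-cost predictions on the natural scale."""
    X_new = np.asarray(X_new, dtype=float)
    eta = X_new @ fit.beta
    if fit.transform == "identity":
        return eta
    s = smearing_factors(fit, X_new)
    if fit.transform == "log":
        return np.exp(eta) * s
    return eta**2 + s
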