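"""Registry of the sixteen cost-regression models under comparison.

Every model exposes the same minimal surface — ``fit(data, seed)`` and
``predict(fit, X)`` returning conditional-mean forecasts on the natural
cost scale — so the comparison harness can treat them interchangeably.
Labels follow the naming convention of the healthcare-cost modelling
literature (e.g. GLMSQRTP = GLM, square-root link, Poisson-type variance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable

import numpy as np

from . import cde, glm, parametric, semiparam, transform_ols
from .datasets import CostDataset

__all__ = ["ModelSpec", "MODEL_REGISTRY", "MODEL_LABELS", "get_model"]


@dataclass(frozen=True)
class ModelSpec:
    label: str
    description: str
    fit: Callable[[CostDataset, int], Any]
    predict: Callable[[Any, np.ndarray], np.ndarray]
    converged: Callable[[Any], bool]


def _always(fit) -> bool:
    return True


def _flag(fit) -> bool:
    return bool(getattr(fit, "converged", True))


def _make_registry() -> dict[str, ModelSpec]:
    specs = [
        ModelSpec(
            "OLS", "linear regression on cost levels",
            lambda d, s: transform_ols.fit_transform_ols(d, "identity"),
            transform_ols.retransform_predict, _always,
        ),
        ModelSpec(
            "LOGOLSHET", "OLS on log cost, heteroscedastic smearing",
            lambda d, s: transform_ols.fit_transform_ols(d, "log"),
            transform_ols.retransform_predict, _always,
        ),
        ModelSpec(
            "SQRTOLSHET", "OLS on root cost, heteroscedastic smearing",
            lambda d, s: transform_ols.fit_transform_ols(d, "sqrt"),
            transform_ols.retransform_predict, _always,
        ),
        ModelSpec(
            "GLMLOGP", "quasi-GLM, log link, variance prop. to mean",
            lambda d, s: glm.fit_glm(d, "log", 1), glm.predict_mean, _flag,
        ),
        ModelSpec(
            "GLMLOGG", "quasi-GLM, log link, variance prop. to mean^2",
            lambda d, s: glm.fit_glm(d, "log", 2), glm.predict_mean, _flag,
        ),
        ModelSpec(
            "GLMSQRTP", "quasi-GLM, sqrt link, variance prop. to mean",
            lambda d, s: glm.fit_glm(d, "sqrt", 1), glm.predict_mean, _flag,
        ),
        ModelSpec(
            "GLMSQRTG", "quasi-GLM, sqrt link, variance prop. to mean^2",
            lambda d, s: glm.fit_glm(d, "sqrt", 2), glm.predict_mean, _flag,
        ),
        ModelSpec(
            "LOGNORM", "lognormal ML",
            lambda d, s: parametric.fit_lognormal(d),
            parametric.mean_lognormal, _flag,
        ),
        ModelSpec(
            "GG", "generalized gamma ML",
            lambda d, s: parametric.fit_gg(d), parametric.mean_gg, _flag,
        ),
        ModelSpec(
            "GB2LOG", "generalized beta of the 2nd kind, log link",
            lambda d, s: parametric.fit_gb2(d, "log"), parametric.mean_gb2, _flag,
        ),
        ModelSpec(
            "GB2SQRT", "generalized beta of the 2nd kind, sqrt link",
            lambda d, s: parametric.fit_gb2(d, "sqrt"), parametric.mean_gb2, _flag,
        ),
        ModelSpec(
            "FMMLOGG", "two-component gamma mixture, log link",
            lambda d, s: semiparam.fit_fmm(d, "log", seed=s),
            semiparam.fmm_mean, _flag,
        ),
        ModelSpec(
            "FMMSQRTG", "two-component gamma mixture, sqrt link",
            lambda d, s: semiparam.fit_fmm(d, "sqrt", seed=s),
            semiparam.fmm_mean, _flag,
        ),
        ModelSpec(
            "EEE", "extended estimating equations (Box-Cox link, power variance)",
            lambda d, s: semiparam.fit_eee(d), semiparam.eee_mean, _flag,
        ),
        ModelSpec(
            "CDEM", "conditional density approximation, multinomial logit",
            lambda d, s: cde.fit_cde(d, model="multinomial"), cde.cde_mean, _flag,
        ),
        ModelSpec(
            "CDEO", "conditional density approximation, ordered logit",
            lambda d, s: cde.fit_cde(d, model="ordered"), cde.cde_mean, _flag,
        ),
    ]
    return {m.label: m for m in specs}


MODEL_REGISTRY: dict[str, ModelSpec] = _make_registry()
MODEL_LABELS: tuple[str, ...] = tuple(MODEL_REGISTRY)


def get_model(label: str) -> ModelSpec:
    try:
        return MODEL_REGISTRY[label]
    except KeyError:
        raise KeyError(
            f"unknown model label {label!r}; valid labels: {', '.join(MODEL_LABELS)}"
        ) from None
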