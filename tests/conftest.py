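import numpy as np
import pytest

from costreg.datasets import CostDataset, CovariateSpec, DGPConfig, make_covariates, simulate_costs


@pytest.fixture(scope="session")
def small_design():
    """n=400 design with intercept, one continuous and one binary covariate."""
    rng = np.random.default_rng(42)
    n = 400
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.4, n)])
    return X


@pytest.fixture(scope="session")
def lognormal_data(small_design):
    return simulate_costs(
        small_design,
        DGPConfig("lognormal", np.array([7.0, 0.4, 0.3]), {"sigma": 1.0}),
        seed=11,
    )


@pytest.fixture(scope="session")
def gg_data():
    """n=5000 generalized-gamma sample used for recovery and nesting checks."""
    rng = np.random.default_rng(1)
    n = 5000
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.4, n)])
    return simulate_costs(
        X,
        DGPConfig("generalized_gamma", np.array([1.0, 0.3, -0.2]),
                  {"sigma": 0.8, "kappa": 0.5}),
        seed=2,
    )
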