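import numpy as np
import pytest

from costreg import semiparam as S
from costreg.datasets import CostDataset, DGPConfig, simulate_costs
from costreg.glm import fit_glm


class TestEEELink:
    @pytest.mark.parametrize("lam,index,expected", [
        (1.0, 2.0, 3.0),
        (0.5, 2.0, 4.0),  # (1 + 0.5*2)^2
    ])
    def test_box_cox_values(self, lam, index, expected):
        assert S.eee_link(lam, np.array([index]))[0] == pytest.approx(expected)

    def test_log_link_limit(self):
        val = S.eee_link(1e-8, np.array([2.0]))[0]
        assert val == pytest.approx(np.exp(2.0), abs=1e-6)

    def test_domain_violation_reported(self):
        with pytest.raises(ValueError, match="rows"):
            S.eee_link(1.0, np.array([0.5, -2.0]))


class TestEEEFit:
    def test_recovers_sqrt_link(self):
        rng = np.random.default_rng(12)
        n = 5000
        X = np.column_stack([np.ones(n), rng.uniform(-1, 1, n), rng.binomial(1, 0.4, n)])
        d = simulate_costs(X, DGPConfig("gamma_glm", np.array([5.0, 2.5, 1.0]),
                                        {"alpha": 2.0}, link="sqrt"), seed=5)
        fit = S.fit_eee(d)
        assert fit.converged
        assert abs(fit.lam - 0.5) <= 0.1

    def test_recovers_log_link(self):
        rng = np.random.default_rng(13)
        n = 5000
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.4, n)])
        d = simulate_costs(X, DGPConfig("lognormal", np.array([1.0, 0.8, 0.5]),
                                        {"sigma": 1.0}), seed=6)
        fit = S.fit_eee(d)
        assert fit.converged
        assert abs(fit.lam) <= 0.1

    def test_fixed_parameters_degenerate_to_glm(self, lognormal_data):
        fix = S.fit_eee(lognormal_data, lam_fixed=0.5, theta2_fixed=1.0)
        glm = fit_glm(lognormal_data, "sqrt", 1)
        # mean (0.5 eta + 1)^2 = (X(beta/2) + 1)^2: the sqrt-link GLM index
        converted = 0.5 * fix.beta
        converted[0] += 1.0
        assert np.allclose(converted, glm.beta, atol=1e-6)
        mu_eee = S.eee_mean(fix, lognormal_data.X)
        assert np.allclose(mu_eee, (lognormal_data.X @ glm.beta) ** 2, rtol=1e-6)


class TestFMMLoglik:
    def _data(self):
        rng = np.random.default_rng(14)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.gamma(2.0, np.exp(0.5 + 0.2 * X[:, 1]))
        return CostDataset(X, y, ["const", "x"])

    def test_identical_components_collapse(self):
        d = self._data()
        beta = np.array([0.5, 0.2])
        single = S.FMMParams(pi=[1.0], alpha=[2.0], betas=[beta], link="log")
        for pi1 in (0.3, 0.5, 0.9):
            double = S.FMMParams(pi=[pi1, 1 - pi1], alpha=[2.0, 2.0],
                                 betas=[beta, beta.copy()], link="log")
            assert S.fmm_loglik(double, d) == pytest.approx(S.fmm_loglik(single, d))

    def test_degenerate_weight_equals_component(self):
        d = self._data()
        b1, b2 = np.array([0.5, 0.2]), np.array([1.5, -0.1])
        mix = S.FMMParams(pi=[1.0 - 1e-15, 1e-15], alpha=[2.0, 3.0],
                          betas=[b1, b2], link="log")
        single = S.FMMParams(pi=[1.0], alpha=[2.0], betas=[b1], link="log")
        assert S.fmm_loglik(mix, d) == pytest.approx(S.fmm_loglik(single, d), rel=1e-9)

    def test_density_integrates_to_one(self):
        from scipy import integrate

        params = S.FMMParams(pi=[0.6, 0.4], alpha=[2.0, 3.0],
                             betas=[np.array([0.0]), np.array([1.0])], link="log")
        X1 = np.array([[1.0]])

        def pdf(y):
            d = CostDataset(X1, np.array([y]), ["const"])
            return np.exp(S.fmm_loglik(params, d))

        total, _ = integrate.quad(pdf, 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)


class TestFMMMean:
    def test_sqrt_link_arithmetic(self):
        params = S.FMMParams(pi=[0.5, 0.5], alpha=[1.0, 2.0],
                             betas=[np.array([1.0]), np.array([2.0])], link="sqrt")
        assert S.fmm_mean(params, np.array([[1.0]]))[0] == pytest.approx(4.5)

    def test_log_link_single_component(self):
        params = S.FMMParams(pi=[1.0], alpha=[1.5],
                             betas=[np.array([0.7])], link="log")
        assert S.fmm_mean(params, np.array([[1.0]]))[0] == pytest.approx(1.5 * np.exp(0.7))

    def test_equal_weights_log_link(self):
        params = S.FMMParams(pi=[0.5, 0.5], alpha=[1.0, 2.0],
                             betas=[np.array([0.0]), np.array([0.0])], link="log")
        assert S.fmm_mean(params, np.array([[1.0]]))[0] == pytest.approx(1.5)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(15)
        params = S.FMMParams(pi=[0.7, 0.3], alpha=[2.0, 3.0],
                             betas=[np.array([0.2]), np.array([1.0])], link="log")
        comp = rng.choice(2, size=200_000, p=params.pi)
        scales = np.where(comp == 0, np.exp(0.2), np.exp(1.0))
        alphas = np.where(comp == 0, 2.0, 3.0)
        draws = rng.gamma(alphas, scales)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - S.fmm_mean(params, np.array([[1.0]]))[0]) <= 3 * se


class TestFMMFit:
    def test_recovery_two_component_log_link(self):
        rng = np.random.default_rng(16)
        n = 10_000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        dgp = DGPConfig("gamma_mixture",
                        [np.array([0.0, 0.3]), np.array([2.0, 0.3])],
                        {"pi": np.array([0.7, 0.3]), "alphas": np.array([2.0, 3.0])})
        d = simulate_costs(X, dgp, seed=7)
        fit = S.fit_fmm(d, "log", seed=0)
        assert fit.converged
        assert np.all(np.abs(fit.pi - [0.7, 0.3]) <= 0.05)
        true_means = [2.0 * np.exp(X @ [0.0, 0.3]).mean(),
                      3.0 * np.exp(X @ [2.0, 0.3]).mean()]
        fit_means = [fit.alpha[j] * np.exp(X @ fit.betas[j]).mean() for j in range(2)]
        assert np.all(np.abs(np.array(fit_means) / true_means - 1.0) <= 0.05)

    def test_mixture_nests_single_gamma(self):
        rng = np.random.default_rng(17)
        n = 3000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        d = simulate_costs(X, DGPConfig("gamma_glm", np.array([0.5, 0.2]),
                                        {"alpha": 2.0}), seed=8)
        single = S.fit_fmm(d, "log", C=1)
        double = S.fit_fmm(d, "log", C=2, seed=1)
        assert double.loglik >= single.loglik - 1e-6
        assert double.loglik - single.loglik < 20.0  # no spurious structure

    def test_canonical_component_order(self):
        rng = np.random.default_rng(18)
        n = 4000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        dgp = DGPConfig("gamma_mixture",
                        [np.array([0.0, 0.3]), np.array([2.0, 0.3])],
                        {"pi": np.array([0.5, 0.5]), "alphas": np.array([2.0, 2.0])})
        d = simulate_costs(X, dgp, seed=9)
        fits = [S.fit_fmm(d, "log", seed=s) for s in (0, 99)]
        for f in fits:
            m = [f.alpha[j] * np.exp(X @ f.betas[j]).mean() for j in range(2)]
            assert m[0] <= m[1]  # label-switching guard
        assert np.allclose(fits[0].pi, fits[1].pi, atol=0.02)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(19)
        X = np.column_stack([np.ones(2000), rng.normal(size=2000)])
        d = simulate_costs(X, DGPConfig("gamma_glm", np.array([0.5, 0.2]),
                                        {"alpha": 2.0}), seed=10)
        fit = S.fit_fmm(d, "log", seed=2)
        assert fit.pi.sum() == pytest.approx(1.0)
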