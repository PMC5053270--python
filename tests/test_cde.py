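import numpy as np
import pytest

from costreg import cde as C
from costreg.datasets import CostDataset, DGPConfig, simulate_costs


class TestPartition:
    def test_fifteen_singletons(self):
        part = C.build_partition(np.arange(1.0, 16.0), Q=15)
        assert part.Q == 15
        assert np.allclose(part.bin_means, np.arange(1.0, 16.0))

    def test_quartile_split_equal_counts(self):
        part = C.build_partition(np.arange(1.0, 101.0), Q=4)
        assert np.all(part.bin_counts == 25)
        assert part.boundaries[0] == 1.0 and part.boundaries[-1] == 100.0

    def test_heavy_tail_top_bin_dominates(self):
        rng = np.random.default_rng(20)
        y = rng.lognormal(7, 1.3, 20_000)
        part = C.build_partition(y, Q=15)
        assert part.bin_means[-1] > 5 * np.median(y)

    def test_mass_points_merged_with_warning(self):
        y = np.concatenate([np.full(500, 10.0), np.arange(1.0, 101.0)])
        with pytest.warns(UserWarning, match="mass points"):
            part = C.build_partition(y, Q=10)
        assert 2 <= part.Q < 10

    def test_too_few_distinct_values_raises(self):
        with pytest.raises(ValueError, match="distinct"):
            C.build_partition(np.array([1.0, 2.0, 2.0, 2.0]), Q=4)

    def test_boundary_ties_go_to_lower_interval(self):
        part = C.build_partition(np.arange(1.0, 101.0), Q=4)
        b1 = part.boundaries[1]
        lab = C.assign_intervals(part, np.array([b1]))
        assert lab[0] == 0


class TestProbabilities:
    def test_mnl_zero_coefficients_uniform(self):
        part = C.IntervalPartition(Q=5, boundaries=np.arange(6.0),
                                   bin_means=np.arange(5.0) + 0.5,
                                   bin_counts=np.ones(5, int))
        params = C.CDEParams(partition=part, model="multinomial",
                             mnl_betas=np.zeros((2, 5)))
        probs = C.interval_probs(params, np.array([[1.0, 2.0]]))
        assert np.allclose(probs, 0.2)

    def test_ordered_logit_symmetric_split(self):
        part = C.IntervalPartition(Q=2, boundaries=np.array([0.0, 1.0, 2.0]),
                                   bin_means=np.array([0.5, 1.5]),
                                   bin_counts=np.ones(2, int))
        params = C.CDEParams(partition=part, model="ordered",
                             ol_psi=np.array([0.0]), ol_beta=np.array([1.0]))
        probs = C.interval_probs(params, np.array([[1.0, 0.0]]))
        assert np.allclose(probs, [0.5, 0.5])

    @pytest.mark.parametrize("p,expected", [
        ([0.5, 0.25, 0.25], [0.5, 0.5, 1.0]),
        ([0.25, 0.25, 0.25, 0.25], [0.25, 1 / 3, 0.5, 1.0]),
    ])
    def test_hazard_values(self, p, expected):
        lam = C.probs_to_hazards(np.array(p))
        assert np.allclose(lam[0], expected)

    def test_hazard_round_trip_identity(self):
        rng = np.random.default_rng(21)
        probs = rng.dirichlet(np.ones(8), size=50)
        back = C.hazards_to_probs(C.probs_to_hazards(probs))
        assert np.allclose(back, probs, atol=1e-12)

    def test_exhausted_support_hazard_is_one(self):
        lam = C.probs_to_hazards(np.array([1.0, 0.0, 0.0]))
        assert np.allclose(lam[0], [1.0, 1.0, 1.0])


@pytest.fixture(scope="module")
def fitted_cde(lognormal_data_module):
    d = lognormal_data_module
    part = C.build_partition(d.y, Q=10)
    mnl = C.fit_cde(d, part, "multinomial")
    ordered = C.fit_cde(d, part, "ordered")
    return d, part, mnl, ordered


@pytest.fixture(scope="module")
def lognormal_data_module():
    rng = np.random.default_rng(22)
    n = 2000
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.4, n)])
    return simulate_costs(X, DGPConfig("lognormal", np.array([7.0, 0.6, 0.4]),
                                       {"sigma": 1.0}), seed=12)


class TestFit:
    def test_intercept_only_mnl_matches_shares(self, lognormal_data_module):
        d = lognormal_data_module
        d0 = CostDataset(np.ones((d.n, 1)), d.y, ["const"])
        part = C.build_partition(d.y, Q=10)
        fit = C.fit_cde(d0, part, "multinomial")
        probs = C.interval_probs(fit, d0.X[:1])
        shares = part.bin_counts / part.bin_counts.sum()
        assert np.allclose(probs[0], shares, atol=1e-6)
        # probability-weighted bin means then reproduce the sample mean
        assert C.cde_mean(fit, d0.X[:1])[0] == pytest.approx(d.y.mean(), rel=1e-6)

    def test_probabilities_normalized(self, fitted_cde):
        d, part, mnl, ordered = fitted_cde
        for fit in (mnl, ordered):
            probs = C.interval_probs(fit, d.X)
            assert np.all(probs >= 0)
            assert np.allclose(probs.sum(axis=1), 1.0)

    def test_mnl_nests_ordered_logit(self, fitted_cde):
        d, part, mnl, ordered = fitted_cde
        lab = C.assign_intervals(part, d.y)
        idx = np.arange(d.n)
        ll_m = np.log(C.interval_probs(mnl, d.X)[idx, lab]).sum()
        ll_o = np.log(C.interval_probs(ordered, d.X)[idx, lab]).sum()
        assert ll_m >= ll_o

    def test_ordered_logit_recovers_index_sign(self, fitted_cde):
        d, part, mnl, ordered = fitted_cde
        # costs increase with x1 and x2, so the ordered index must too
        assert ordered.ol_beta[0] > 0 and ordered.ol_beta[1] > 0

    def test_predictions_bounded_by_bin_means(self, fitted_cde):
        d, part, mnl, ordered = fitted_cde
        for fit in (mnl, ordered):
            pred = C.cde_mean(fit, d.X)
            assert np.all(pred >= part.bin_means.min() - 1e-9)
            assert np.all(pred <= part.bin_means.max() + 1e-9)

    def test_degenerate_probability_returns_bin_mean(self):
        part = C.IntervalPartition(Q=3, boundaries=np.arange(4.0),
                                   bin_means=np.array([10.0, 20.0, 30.0]),
                                   bin_counts=np.ones(3, int))
        big = 50.0
        params = C.CDEParams(partition=part, model="multinomial",
                             mnl_betas=np.array([[0.0, big, 0.0]]))
        assert C.cde_mean(params, np.array([[1.0]]))[0] == pytest.approx(20.0)

    def test_uniform_probs_average_bin_means(self):
        part = C.IntervalPartition(Q=15, boundaries=np.arange(16.0),
                                   bin_means=np.arange(1.0, 16.0),
                                   bin_counts=np.ones(15, int))
        params = C.CDEParams(partition=part, model="multinomial",
                             mnl_betas=np.zeros((1, 15)))
        assert C.cde_mean(params, np.array([[1.0]]))[0] == pytest.approx(8.0)
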