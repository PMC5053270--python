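import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from costreg import evaluation as E
from costreg.datasets import CostDataset, DGPConfig, simulate_costs
from costreg.glm import fit_glm, predict_mean
from costreg.transform_ols import fit_transform_ols, retransform_predict


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        rec = E.compute_metrics(y, y.copy())
        assert rec.mpe == rec.mape == rec.rmse == 0.0

    def test_arithmetic_example(self):
        rec = E.compute_metrics(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]))
        assert rec.mpe == pytest.approx(0.0)
        assert rec.mape == pytest.approx(2.0 / 3.0)
        assert rec.rmse == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            E.compute_metrics(np.ones(3), np.ones(4))

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.tuples(
        st.floats(1.0, 1e5), st.floats(1.0, 1e5)), min_size=1, max_size=40))
    def test_power_mean_ordering(self, pairs):
        y = np.array([p[0] for p in pairs])
        yhat = np.array([p[1] for p in pairs])
        rec = E.compute_metrics(y, yhat)
        assert rec.rmse >= rec.mape - 1e-9
        assert rec.mape >= abs(rec.mpe) - 1e-9

    def test_translation_shifts_mpe(self):
        rng = np.random.default_rng(23)
        y = rng.lognormal(7, 1, 500)
        yhat = y * rng.uniform(0.8, 1.2, 500)
        base = E.compute_metrics(y, yhat)
        shifted = E.compute_metrics(y, yhat + 100.0)
        assert shifted.mpe == pytest.approx(base.mpe - 100.0)

    def test_admpe_single_replication_is_zero(self):
        rec = E.compute_metrics(np.ones(5), np.zeros(5), model="m", sample_size=100,
                                replication=0)
        E.add_admpe([rec])
        assert rec.admpe == 0.0

    def test_admpe_across_replications(self):
        recs = []
        for r, mpe_target in enumerate([10.0, 20.0, 30.0]):
            y = np.full(4, 100.0)
            recs.append(E.compute_metrics(y, y - mpe_target, model="m",
                                          sample_size=50, replication=r))
        E.add_admpe(recs)
        assert [r.admpe for r in recs] == pytest.approx([10.0, 0.0, 10.0])


class TestPearson:
    def test_ols_in_sample_not_applicable_logic(self, lognormal_data):
        fit = fit_transform_ols(lognormal_data, "identity")
        pred = retransform_predict(fit, lognormal_data.X)
        res = E.pearson_test(lognormal_data.y, pred)
        # OLS residuals are orthogonal to fitted values by construction
        assert res.slope == pytest.approx(0.0, abs=1e-10)
        assert not res.reject_5pct

    def test_constant_shift_slope_zero(self):
        y = np.random.default_rng(24).lognormal(7, 1, 300)
        res = E.pearson_test(y, y + 50.0)
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictions_not_applicable(self):
        res = E.pearson_test(np.array([1.0, 2.0, 3.0]), np.full(3, 2.0))
        assert not res.applicable

    def test_type_one_error_calibrated(self):
        # correctly specified gamma GLM: ~5% rejections at the 5% level
        rng = np.random.default_rng(25)
        n = 400
        rejections = 0
        n_rep = 200
        for r in range(n_rep):
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            d = simulate_costs(X, DGPConfig("gamma_glm", np.array([1.0, 0.4]),
                                            {"alpha": 2.0}), seed=1000 + r)
            fit = fit_glm(d, "log", 2)
            res = E.pearson_test(d.y, predict_mean(fit, X))
            rejections += res.reject_5pct
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.08


class TestDeciles:
    def test_constant_shift(self):
        rng = np.random.default_rng(26)
        y = rng.lognormal(7, 1, 200)
        profs = E.decile_profile(y, y + 10.0)
        assert len(profs) == 10
        for p in profs:
            assert p.mpe == pytest.approx(-10.0)

    def test_ten_observations_individual_errors(self):
        y = np.arange(10.0)
        yhat = np.arange(10.0) + np.linspace(-1, 1, 10)
        profs = E.decile_profile(y, yhat)
        errors = y - yhat
        order = np.argsort(yhat, kind="stable")
        for p, idx in zip(profs, order):
            assert p.n == 1
            assert p.mpe == pytest.approx(errors[idx])

    def test_partition_sizes_near_equal(self):
        y = np.random.default_rng(27).lognormal(7, 1, 1003)
        profs = E.decile_profile(y, y * 1.1)
        sizes = [p.n for p in profs]
        assert sum(sizes) == 1003
        assert max(sizes) - min(sizes) <= 1


class TestResponseSurface:
    def _records(self, values_by_ns):
        recs = []
        for ns, vals in values_by_ns.items():
            for r, v in enumerate(vals):
                recs.append(E.MetricRecord(model="m", sample_size=ns, replication=r,
                                           mpe=v, mape=abs(v) + 1.0,
                                           rmse=abs(v) + 2.0, n_eval=ns))
        return recs

    def test_flat_metric_zero_slope(self):
        recs = self._records({1000: [5.0, 5.0], 5000: [5.0, 5.0]})
        rs = E.fit_response_surface(recs, "m", "MPE")
        assert rs.alpha == pytest.approx(5.0)
        assert rs.beta_inv_n == pytest.approx(0.0, abs=1e-9)

    def test_two_points_exact_line(self):
        recs = self._records({5000: [1.0], 10000: [2.0]})
        rs = E.fit_response_surface(recs, "m", "MPE")
        pred1 = rs.alpha + rs.beta_inv_n / 5000
        pred2 = rs.alpha + rs.beta_inv_n / 10000
        assert pred1 == pytest.approx(1.0)
        assert pred2 == pytest.approx(2.0)

    def test_recovers_alpha_beta_within_ci(self):
        rng = np.random.default_rng(28)
        alpha, beta = 3.0, 4000.0
        recs = []
        for ns in (1000, 2000, 5000, 10000):
            for r in range(30):
                v = alpha + beta / ns + rng.normal(0, 0.5)
                recs.append(E.MetricRecord(model="m", sample_size=ns, replication=r,
                                           mpe=v, mape=abs(v) + 1, rmse=abs(v) + 2,
                                           n_eval=ns))
        rs = E.fit_response_surface(recs, "m", "MPE")
        assert abs(rs.alpha - alpha) <= 1.96 * rs.alpha_se
        assert abs(rs.beta_inv_n - beta) <= 1.96 * rs.beta_se

    def test_log_specification_rejects_nonpositive(self):
        recs = self._records({1000: [-5.0], 5000: [-5.0]})
        for r in recs:
            r.mape = -1.0  # impossible, to exercise the guard
        with pytest.raises(ValueError):
            E.fit_response_surface(recs, "m", "MAPE")
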