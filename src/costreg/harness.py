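"""Quasi-Monte-Carlo model comparison.

The design: a large synthetic population is split once into equally sized
estimation and validation halves.  From the estimation half, samples of
size Ns are drawn with replacement R times; every model is fitted on each
sample, forecasts are evaluated on the full validation half (out of
sample) and the Pearson misspecification test is run on the sample used
for estimation (in sample).  Only replications where every requested model
converged enter the summaries, so all models are compared on identical
draws.  Per-replication seeds are derived from (master seed, Ns, r), so a
run is bit-reproducible and independent of execution order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import (CostDataset, CovariateSpec, DGPConfig, make_covariates,
                       simulate_costs, split_population, heavy_tail_cost_config)
from .evaluation import (MetricRecord, add_admpe, compute_metrics, decile_profile,
                         fit_response_surface, pearson_test)
from .models import MODEL_LABELS, get_model

__all__ = ["HarnessConfig", "ReplicationResult", "ExperimentResults",
           "build_population", "run_experiment", "summarize", "response_surfaces",
           "DESK_MODELS"]

# a desk-scale model list: every estimator family is represented but the
# heaviest optimizers are limited to one variant each
DESK_MODELS = ("OLS", "LOGOLSHET", "SQRTOLSHET", "GLMLOGP", "GLMLOGG",
               "GLMSQRTP", "GLMSQRTG", "LOGNORM")


@dataclass
class HarnessConfig:
    population_size: int = 200_000
    sample_sizes: tuple[int, ...] = (1000, 5000)
    replications: int = 20
    model_list: tuple[str, ...] = DESK_MODELS
    master_seed: int = 0
    dgp: DGPConfig | None = None  # default: the packaged heavy-tail config
    covariate_spec: CovariateSpec | None = None

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("need at least one replication")
        bad = set(self.model_list) - set(MODEL_LABELS)
        if bad:
            raise ValueError(f"unknown model labels: {sorted(bad)}")
        if max(self.sample_sizes) > self.population_size // 2:
            raise ValueError("sample sizes must not exceed the estimation half")


@dataclass
class ReplicationResult:
    sample_size: int
    replication: int
    converged: dict[str, bool]
    metrics: dict[str, MetricRecord]
    pearson: dict[str, object]
    deciles: dict[str, list]
    included: bool = False


@dataclass
class ExperimentResults:
    config: HarnessConfig
    replications: list[ReplicationResult] = field(default_factory=list)

    def included(self) -> list[ReplicationResult]:
        return [r for r in self.replications if r.included]

    def metric_records(self, included_only: bool = True) -> list[MetricRecord]:
        reps = self.included() if included_only else self.replications
        recs = [rec for rep in reps for rec in rep.metrics.values()]
        return add_admpe(recs)

    def metrics_frame(self, included_only: bool = True) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r)
                             for r in self.metric_records(included_only)])


def _child_seed(master: int, *parts: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(p) for p in parts))


def build_population(config: HarnessConfig) -> CostDataset:
    """Simulate the population implied by the config (the packaged
    heavy-tail configuration unless a DGP is supplied)."""
    spec, dgp = config.covariate_spec, config.dgp
    if dgp is None:
        default_spec, dgp = heavy_tail_cost_config(config.population_size)
        spec = spec or default_spec
    elif spec is None:
        spec = CovariateSpec(n=config.population_size)
    spec = dataclasses.replace(spec, n=config.population_size)
    seeds = _child_seed(config.master_seed, 0).generate_state(2)
    X = make_covariates(spec, seed=int(seeds[0]))
    return simulate_costs(X, dgp, seed=int(seeds[1]))


def _fit_one(label: str, sample: CostDataset, seed: int):
    spec = get_model(label)
    try:
        fit = spec.fit(sample, seed)
        ok = spec.converged(fit)
        return fit, bool(ok)
    except Exception:
        return None, False


def run_experiment(config: HarnessConfig,
                   population: CostDataset | None = None,
                   verbose: bool = False) -> ExperimentResults:
    """Run the full design; any model failure on a draw is recorded as
    non-convergence for that replication, never aborts the run."""
    if population is None:
        population = build_population(config)
    est, val = split_population(population, seed=int(
        _child_seed(config.master_seed, 1).generate_state(1)[0]))
    results = ExperimentResults(config=config)
    for Ns in config.sample_sizes:
        for r in range(config.replications):
            ss = _child_seed(config.master_seed, 2, Ns, r)
            draw_rng = np.random.default_rng(ss)
            idx = draw_rng.integers(0, est.n, size=Ns)  # with replacement
            sample = est.subset(idx)
            model_seeds = ss.generate_state(len(config.model_list) + 1)[1:]
            rep = ReplicationResult(sample_size=Ns, replication=r,
                                    converged={}, metrics={}, pearson={}, deciles={})
            for label, mseed in zip(config.model_list, model_seeds):
                fit, ok = _fit_one(label, sample, int(mseed) % (2**31))
                rep.converged[label] = ok
                if not ok:
                    continue
                spec = get_model(label)
                try:
                    yhat_val = np.asarray(spec.predict(fit, val.X), dtype=float)
                    yhat_est = np.asarray(spec.predict(fit, sample.X), dtype=float)
                    if not np.all(np.isfinite(yhat_val)):
                        raise FloatingPointError("non-finite predictions")
                    rep.metrics[label] = compute_metrics(
                        val.y, yhat_val, model=label, sample_size=Ns, replication=r)
                    rep.pearson[label] = pearson_test(sample.y, yhat_est)
                    rep.deciles[label] = decile_profile(val.y, yhat_val, model=label)
                except Exception:
                    rep.converged[label] = False
            rep.included = all(rep.converged.get(m, False) for m in config.model_list)
            # a failed prediction invalidates the replication's joint filter
            if rep.included:
                rep.metrics = {m: rep.metrics[m] for m in config.model_list}
            results.replications.append(rep)
            if verbose:
                failed = [m for m, ok in rep.converged.items() if not ok]
                msg = "ok" if rep.included else f"dropped (failed: {', '.join(failed)})"
                print(f"Ns={Ns} r={r}: {msg}")
    return results


def summarize(results: ExperimentResults) -> dict[str, pd.DataFrame]:
    """Per-model averages over included replications: MPE/MAPE/RMSE/ADMPE
    (one table per sample size, best-four flags per column) and Pearson
    rejection percentages."""
    included = results.included()
    if not included:
        raise ValueError("no replication had all requested models converge")
    recs = results.metrics_frame()
    perf = (recs.groupby(["sample_size", "model"])
            [["mpe", "mape", "rmse", "admpe"]].mean().reset_index())
    flags = []
    for ns, grp in perf.groupby("sample_size"):
        g = grp.copy()
        g["best4_mpe"] = g["mpe"].abs().rank(method="min") <= 4
        for col in ("mape", "rmse"):
            g[f"best4_{col}"] = g[col].rank(method="min") <= 4
        flags.append(g)
    perf = pd.concat(flags, ignore_index=True)

    rows = []
    for rep in included:
        for label, test in rep.pearson.items():
            rows.append((rep.sample_size, label, test.applicable,
                         bool(test.reject_5pct)))
    pearson = pd.DataFrame(rows, columns=["sample_size", "model", "applicable", "reject"])
    rej = (pearson[pearson.applicable]
           .groupby(["sample_size", "model"])["reject"].mean()
           .mul(100.0).rename("rejection_pct").reset_index())

    dec_rows = []
    for rep in included:
        for label, profs in rep.deciles.items():
            for p in profs:
                dec_rows.append((rep.sample_size, label, p.decile, p.mpe, p.mape))
    deciles = (pd.DataFrame(dec_rows,
                            columns=["sample_size", "model", "decile", "mpe", "mape"])
               .groupby(["sample_size", "model", "decile"]).mean().reset_index())

    counts = pd.DataFrame(
        [(ns, sum(1 for r in results.replications
                  if r.sample_size == ns and r.included),
          sum(1 for r in results.replications if r.sample_size == ns))
         for ns in results.config.sample_sizes],
        columns=["sample_size", "included", "total"])
    return {"performance": perf, "pearson": rej, "deciles": deciles,
            "included": counts}


def response_surfaces(results: ExperimentResults,
                      metrics: tuple[str, ...] = ("MPE", "MAPE", "RMSE", "ADMPE"),
                      ) -> pd.DataFrame:
    """Response-surface fits (metric or log metric against 1/Ns) for every
    model in the run; requires at least two distinct sample sizes."""
    recs = results.metric_records()
    rows = []
    for label in results.config.model_list:
        for metric in metrics:
            rs = fit_response_surface(recs, label, metric)
            rows.append(dataclasses.asdict(rs))
    return pd.DataFrame(rows)
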