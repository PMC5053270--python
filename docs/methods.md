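# Methods

## Scope and design

`costreg` estimates and compares regression models for the conditional
mean of strictly positive, heavy-tailed cost outcomes.  Everything is
organized around three contracts:

- a `CostDataset` (design matrix with leading intercept, positive outcome
  vector);
- a model surface: `fit(data) -> params` with a `converged` flag, and a
  conditional-mean predictor on the natural cost scale;
- an experiment: estimation/validation split, repeated with-replacement
  sampling, out-of-sample metric evaluation, joint convergence filtering.

## Distributional models

**Transformed OLS with smearing.**  OLS on y, ln y or √y.  Retransforming
a log- or root-scale prediction to the cost scale needs the conditional
moment of the residual: E[y|X] = exp(Xβ)·E[e^ε|X] for the log transform
and E[y|X] = (Xβ)² + E[ε²|X] for the root transform.  Both corrections
are estimated, as Duan-type smearing, by a second OLS of the transformed
residual (e^ε, or ε²) on the same covariates, which makes the correction
covariate-dependent under heteroscedasticity.  The correction is
multiplicative for the log transform and additive for the square-root
transform — forced by the two moment identities above.  Because a linear
projection of a positive quantity can dip negative in the tails, fitted
smearing values are floored (at 10⁻⁶ for log, 0 for sqrt).  A
constant-smearing (homoscedastic) variant exists for diagnostics.

**Quasi-likelihood GLMs.**  Mean μ = g⁻¹(Xβ) with g ∈ {log, √}; variance
V(μ) = φμ (Poisson-type) or φμ² (gamma-type).  β solves the quasi-score
equations Σ (∂μ/∂β)(y−μ)/V(μ) = 0; only the first two moments are
assumed, so coefficients are consistent whenever the mean is right.
Fitting is statsmodels' IRLS started at OLS on the link-transformed
outcome (which keeps the √-link index positive in practice); dispersion
comes from Pearson residuals.  An estimate is flagged non-converged if
IRLS fails, any fitted mean is non-positive, or (√ link) the index is
non-positive on an estimation row.

**Parametric maximum likelihood.**  Lognormal (ML = least squares on
logs), generalized gamma (GG), and generalized beta of the second kind
(GB2), all with a single scale parameter driven by the linear index and
global shape parameters:

- GG(σ, κ): density |κ| z^(1/κ²) e^(−z) / (σ y Γ(1/κ²)) with
  z = κ⁻²(y/exp(Xβ))^(κ/σ); mean exp(Xβ)(κ²)^(σ/κ)Γ(1/κ²+σ/κ)/Γ(1/κ²).
  The family tends to the lognormal as κ→0, where the direct expression
  degenerates numerically: below |κ| < 10⁻³ the likelihood switches to the
  lognormal limit.  This also guarantees the fitted GG likelihood is never
  below the lognormal one, because one optimizer start sits exactly at the
  closed-form lognormal solution.
- GB2(a, p, q): density a y^(ap−1) / {b^(ap) B(p,q) [1+(y/b)^a]^(p+q)}
  with b(X) = exp(Xβ) or (Xβ)²; mean b(X)Γ(p+1/a)Γ(q−1/a)/(Γ(p)Γ(q)),
  finite only for q > 1/a (violations raise an explicit error).  The
  likelihood is optimized in (β, ln a, ln p, ln q) with multiple starts:
  moderate-tail, log-logistic-like, heavy-tail, and (log link) two starts
  derived from the GG fit along the q→∞ ridge on which the GB2 approaches
  the GG.  The ridge gap decays as O(1/q), so the q = 5·10⁴ start places
  the optimizer within ~10⁻⁴ log-likelihood units of the GG optimum and
  the nesting inequality lognormal ≤ GG ≤ GB2 holds by construction up to
  optimizer tolerance.  All densities are computed through `gammaln` /
  `logaddexp`, so extreme costs cannot overflow.

**Finite gamma mixtures.**  f(y|X) = Σⱼ πⱼ fⱼ(y|X) with two gamma
components, each with shape αⱼ and scale exp(Xβⱼ) (log link) or (Xβⱼ)²
(√ link); mean Σⱼ πⱼαⱼ·linkinv(Xβⱼ).  Estimation is EM: responsibilities
in the E-step; in the M-step each component's mean coefficients solve a
responsibility-weighted quasi-gamma IRLS and its shape solves
ψ(α) − ln α = 1 + Σw(ln(y/m) − y/m)/Σw.  The √-link quasi-score can have
several roots, and an unguarded warm-started IRLS was observed to hop
between them, producing small limit cycles in the EM log-likelihood; IRLS
steps are therefore accepted only if they do not decrease the weighted
objective −Σw(y/m + ln m), restoring monotone EM.  Five random starts plus
one k-means-on-ln(y) start are ranked by short EM runs (40 iterations);
the winner is polished to convergence (tolerance 10⁻⁸ relative, up to 600
iterations).  Components are reported in increasing order of component
mean, so output is invariant to label switching; a vanishing weight
(π < 10⁻³) or exploding shape (α > 10⁴) is flagged as non-convergence.

**Extended estimating equations.**  Mean (λXβ+1)^(1/λ) (Box–Cox link:
λ = 0 log, λ = 0.5 square root), variance θ₁μ^θ₂.  Estimation profiles
everything but λ: for fixed λ, β solves the quasi-score by IRLS and
(θ₁, θ₂) solve a quasi-gamma regression of squared residuals on ln μ,
iterated to a joint fixed point; λ is then the root of its own profiled
quasi-score Σ(∂μ/∂λ)(y−μ)/μ^θ₂ = 0, bracketed on a grid over [−0.5, 1.5].
Every estimating equation has zero expectation at the truth when the mean
specification is correct.  An earlier Gaussian profile-likelihood
formulation was rejected during development: its λ estimate drifted away
from the true link under heavy skew, while the estimating-equation
formulation recovers λ within ~0.05 of 0 (lognormal data) and ~0.07 of
0.5 (√-link gamma data) at n = 5000.  On very heavy-tailed draws the
profiled score can skim zero without crossing; the |score| minimizer is
then accepted iff the score there is within two (plug-in) standard errors
of zero, otherwise the fit is flagged non-converged — occasional EEE
failures at small samples are expected behavior of this estimator class,
and the harness's convergence filter absorbs them.

**Conditional density approximation.**  The estimation-sample cost range
is cut into Q = 15 intervals; "equally sized" is implemented as
equal-probability (quantile) boundaries, because with skewness above 10
equal-width bins would be nearly all empty and the logit models
unestimable.  Ties at a boundary go to the lower interval (deterministic
rule); mass points that collapse adjacent quantiles are merged with a
warning.  Interval membership is modelled by multinomial logit (first
interval's coefficients normalized to zero) or ordered logit (Q−1
increasing thresholds; the intercept is absorbed by them), both fitted by
statsmodels ML; interval probabilities are recomputed from the extracted
parameters with log-sum-exp in package code.  The mean forecast is
Σⱼ pⱼ(X)ȳⱼ with bin means frozen at estimation-sample values, so
predictions are bounded by the extreme bin means — this estimator cannot
extrapolate beyond observed costs, a structural contrast with the
parametric families.  The probabilities factor exactly into discrete
hazards λⱼ = pⱼ/(1−Σ_{l<j} p_l) (hazard 1 beyond exhausted support), and
the round trip probabilities ↔ hazards is an algebraic identity used as a
test invariant.

## Out-of-sample predictions at the domain boundary

√-link and Box–Cox-link indices fitted on a sample can go negative for
validation covariate combinations outside the sample's range.  The mean
functions extend naturally: (Xβ)² is used as-is for √-link scales, and
Box–Cox means are floored at zero cost where λXβ+1 < 0 (the monotone
limit of the link).  Positivity is enforced only during estimation, where
the density requires it.

## Synthetic populations

The generator draws a design matrix of intercept, centred-and-scaled age
(integer years, quarter-range scaling, so the cubic polynomial stays well
conditioned and the scaling constants are fixed by the age range rather
than the sample), gender, full gender×age interactions, and 24 Bernoulli
morbidity markers with geometrically decreasing prevalences
(0.3·0.85^j) that mimic common-to-rare diagnostic groups without claiming
clinical meaning.  Outcomes can be drawn from any of the estimable
families (lognormal, GG, GB2, gamma GLM, gamma mixture) with the closed
form conditional mean of that family, so every estimator can be validated
by parameter recovery on its own data-generating process.  An optional
rounding-to-tariff step (off by default) snaps costs to a currency grid to
emulate administrative mass points.

The packaged heavy-tail configuration uses a lognormal conditional law
with σ² = 1.42 and covariate index variance ≈ 0.25, its intercept
calibrated once so the marginal distribution has mean ≈ 2600 currency
units at ≈ 2.3× the median with skewness well above 10 and variance
increasing in the conditional mean — the signature of annual inpatient
cost data.  What the generator does not emulate: discreteness from tariff
schedules (unless the rounding option is on), zero costs (non-users are
out of scope; all outcomes are strictly positive), clustering within
providers, and any real covariate-morbidity dependence structure
(markers are independent Bernoullis).  Passing tests therefore demonstrate
correctness of the estimators and the comparison machinery under a
realistic shape, not fidelity to any particular administrative dataset.

## The comparison harness

The population is split once into equal halves.  For each sample size Ns
and replication r, a with-replacement sample of the estimation half is
drawn (duplicates are expected and allowed), every model is fitted,
forecasts are evaluated on the entire validation half, and the Pearson
test (OLS of raw residuals on predictions, two-sided t at 5%) runs on the
estimation draw.  Metric divisors are always the number of evaluated
observations.  A replication enters the summaries only if every requested
model converged, so all models face identical draws; any model exception
is caught and recorded as non-convergence, never aborting the run.
Per-replication seeds derive from SeedSequence(master, Ns, r), making runs
bit-reproducible and order-independent.  Decile profiles (stable sort by
prediction, ten near-equal groups) are averaged across included
replications.  Response surfaces regress MPE (or the log of MAPE, RMSE,
ADMPE, which are positive) on 1/Ns; the intercept's t-test against zero
(t distribution, n−2 df) indicates whether an estimator's bias vanishes
asymptotically.

Shipped problem sizes are desk scale — population 200,000, Ns ∈ {1000,
5000}, R = 20 for the eight fast models, and R = 5 with all sixteen for
the acceptance script — chosen so a full comparison runs in minutes on a
single CPU while leaving the architecture identical at larger scale.
Findings at Ns = 1000 (e.g. occasional EEE/GB2SQRT non-convergence, the
average estimated Box–Cox λ ≈ 0.5 on the heavy-tailed population despite
its log-link truth) reflect small-sample behavior under extreme kurtosis
and tighten toward the textbook asymptotics as Ns grows.

## Numerical choices

- GG κ is estimated unconstrained; |κ| < 10⁻³ routes through the
  lognormal limit.
- L-BFGS-B with numerical gradients everywhere a closed-form solution is
  unavailable; evaluation budgets sized for designs with dozens of
  columns, and a non-`success` incumbent is restarted once with fresh
  curvature memory before being flagged.
- Rank-deficient designs raise (they are reported, not silently dropped);
  at very small samples rare morbidity columns can be all-zero in a draw,
  which surfaces as a non-converged replication.
- The Pearson test is reported "not applicable" for constant predictions,
  and is structurally zero for in-sample OLS (normal equations).
- Mixture and multinomial likelihoods use log-sum-exp throughout.

## Known limitations

- The EEE λ-bracket [−0.5, 1.5] covers the links of practical interest;
  data favoring λ outside it are flagged rather than extrapolated.
- GB2 standard errors are not reported by the fitters (tests compute
  observed-information errors externally); the focus is mean prediction.
- The CDE implementation fixes Q a priori rather than selecting it by
  penalized fit, and models all hazards through one multinomial/ordered
  specification rather than one logit per interval.
- Only strictly positive costs are modelled; two-part extensions for zero
  costs are out of scope.
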