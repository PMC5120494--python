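# Methods

## The model

Illumina methylation arrays report, at each CpG site, a methylated and an
unmethylated fluorescence intensity (M, U), summarized as the beta value
b = M/(M + U + a) with a stabilizing offset a (usually 100). Beta values are
bounded in (0, 1) with variance that shrinks near the boundaries, and the two
intensities are typically *positively correlated*, which breaks the implicit
independence assumption behind beta regression.

`rcgmeth` models the pair (M, U) as a Wicksell–Kibble bivariate gamma
distribution: common shape α > 0, rates λ_m, λ_u > 0 (so the marginals are
Gamma(α, λ_m) and Gamma(α, λ_u)), and Pearson correlation ρ ∈ [0, 1). The
ratio b = M/(M + U) then has the closed-form density

    f_b(b) ∝ θ^α (1 − ρ)^α (b(1−b))^{α−1} A / D^{α + 1/2},
    A = (θ − 1) b + 1,
    D = A² − 4 ρ θ b (1 − b),

where θ := λ_m / λ_u = E(U)/E(M) is the only function of the rates that is
identifiable from beta values. The regression model links the mean ratio to
covariates by log θ | X = Xᵀγ, so γ_k = 0 means covariate k shifts the two
intensities identically and carries no methylation association. This is the
RCG ("ratio of correlated gammas") model. Special cases: at ρ = 0 and θ = 1
the density is Beta(α, α); at ρ = 0 generally it is the distribution of
G₁/(G₁+G₂) for independent gammas with common shape. The density also obeys
the exact reflection identity f(b; α, ρ, θ) = f(1−b; α, ρ, 1/θ).

The derivation sets a = 0; in practice the model is applied to beta values
as provided (the offset only enters when reconstructing b from raw
intensities in the I/O layer).

## Estimation

The log-likelihood is maximized jointly over (γ, α, ρ) with L-BFGS-B on the
unconstrained parameterization (γ, log α, logit ρ), using the analytic
gradient. The objective is the *mean* log-likelihood so stopping rules are
comparable across sample sizes. A coordinate-wise variant (one parameter at
a time along its partial gradient, with step halving) is available via
`FitSettings(optimizer="coordinate")`; both target the same maximizer.

Two numerical properties of this likelihood shaped the defaults:

* **A near-flat (α, ρ) ridge.** To first order var(b) ≈
  2·(1 − ρ)·mean[(b̄(1 − b̄))²]/α with b̄ = 1/(1 + θ), so the data constrain
  α/(1 − ρ) strongly and the position *along* the ridge only through tail
  shape (e.g. excess kurtosis grows with ρ at fixed variance). Generic
  starts occasionally converge to a secondary local optimum on the ridge.
  The initializer therefore scans a fixed ρ grid {0.05 … 0.97}, matches α to
  the residual variance of b at each candidate, and starts from the most
  likely pair; γ is initialized from an M-value least-squares fit scaled by
  −log 2 (the mean-ratio link is approximately the negative natural-log
  logit of E(b)).
* **Flatness along the ridge defeats function-change stopping rules.** The
  relative-change tolerance is deliberately extreme (ftol = 1e−14 on the
  mean log-likelihood) so the optimizer keeps walking the ridge until the
  gradient criterion (max component < 1e−5 per observation, with up to 3
  deterministic jittered restarts) decides convergence. In cohort-sized
  simulations (n = 1118) this converges in well under 200 iterations and a
  few tens of milliseconds.

A fit never silently degrades the likelihood: if the optimizer ends below
the initializer's log-likelihood the initial parameters are returned with
`converged=False`.

### Standard errors and tests

Wald tests use Z_k = γ̂_k / √(J⁻¹)_kk with J the γ-block of the observed
information (central differences of the analytic γ-gradient) evaluated at
(γ̂, α̂, ρ̂), i.e. with the hyperparameters plugged in. This ignores the
sampling variability of (α̂, ρ̂); `observed_information(..., mode="full")`
instead inverts the full (p+3)-parameter Hessian and extracts the γ-block,
propagating hyperparameter uncertainty. On well-specified cohort-sized
simulations the two differ by well under 10% and the plug-in version is the
default. Two-sided p-values are standard normal; k = 0 (the intercept) can
be tested but is flagged as not a methylation-association hypothesis.

## Comparators

* **M-value regression**: ordinary least squares on log₂(b/(1−b)), Wald z
  from the Gaussian observed information (σ̂² = RSS/n), normal p-values —
  the same test form as the RCG model.
* **Beta regression**: logit mean link, constant precision φ, joint ML over
  (coefficients, log φ) with analytic gradients; Wald z from the exact
  observed Hessian of the coefficient block with φ plugged in. The
  implementation is self-contained and is cross-checked in the test suite
  against `statsmodels` `BetaModel` (coefficients, log-likelihood and
  standard errors agree to ~1e−4).

**Log-scores.** Model fit is compared by the mean out-of-sample predictive
log-density — a proper scoring rule, maximized in expectation by the true
data-generating model. All scores are reported on the b scale: the M-value
model's Gaussian score is corrected by the Jacobian log|dM/db| =
−log log 2 − log(b(1−b)) so the three models are directly comparable
(disable with `jacobian=False` to score on the transformed scale).

## Samplers

* **Kibble pairs** are drawn by the exact mixture representation
  M ~ Gamma(α, λ_m); K | M ~ Poisson(ρ λ_m M/(1−ρ));
  U | K ~ Gamma(α + K, λ_u/(1−ρ)), which reproduces the gamma marginals and
  corr(M, U) = ρ (verified by KS distance < 0.005 at 10⁶ draws).
* **Ratio draws** default to the ratio of a Kibble pair (vectorized over
  per-observation θ_i); an inverse-CDF path on a 2048-point trapezoid grid
  is available and agrees in distribution.
* **Gumbel-copula pairs** use the Marshall–Olkin frailty construction with
  a positive stable variate (Chambers–Mallows–Stuck, computed in log space
  to survive large copula parameters); uniforms are pushed through gamma
  quantile functions with per-observation rates exp(Xᵀζ_m), exp(Xᵀζ_u).
  The copula parameter ρ̃ is calibrated to a target Pearson correlation of
  the *gamma-scale* pair by Monte-Carlo root bracketing with common random
  numbers (10⁵ draws per evaluation, tolerance 0.005); the Kendall-τ
  identity τ = 1 − 1/ρ̃ is used as an independent check of the uniforms.
* **Covariates** emulate the printed marginals of a population-based cohort
  of n = 1118: gender Bernoulli(0.479), smoking Bernoulli(0.189), age
  truncated-normal(58.3, 7.3) on the enrolment window [45, 75], BMI
  truncated-normal(27.4, 7.3) floored at 15, and a CES-D-like depression
  score as negative binomial (r = 2.6, p = 0.27), grid-matched to median 6
  and IQR [3, 10]. Columns are generated independently — real cohort
  covariates are correlated (age/BMI/smoking), which the generator does not
  emulate. Rejection rates conditioned on these synthetic covariates can
  therefore differ slightly from rates conditioned on a real cohort's
  design; the simulation tolerances account for this.

## Simulation studies

The power/type-I harness fixes one covariate matrix per study (drawn once
from the study seed) and varies only the beta values across replicates,
mimicking an analysis that conditions on a real cohort's covariates. Two
generators are available: the ratio density itself (well-specified case)
and the Gumbel-copula construction with unequal marginal shapes
(20.2 / 12.760) and the reference ζ coefficient vectors (misspecified
case — the copula's joint law is not a bivariate gamma). Under the null the
tested coefficient is removed from both ζ vectors identically.

Default problem sizes are chosen for desk-scale runs: n = 1118 subjects,
2000 replicates for type-I rates (MC SE ≈ 0.005), 1000 per effect point for
power curves, 200 datasets for recovery/coverage, and 20 train/test splits
of 750/368 for log-score comparisons. Replicates whose RCG fit fails to
converge are re-drawn once, then counted as non-rejections and logged. The
reference single-site parameter set used throughout is
γ = (−1.099, 0.096, −0.007, −0.004, 0.003, 0.001), α = 5.84, ρ = 0.93
(cohort ML estimates at one CpG site; the gender entry is the varied
effect). The multi-site study draws per-site (α, ρ, γ_gender) combinations
from a synthetic table (log-normal shapes around the reference α,
beta-distributed correlations with mean ≈ 0.45, uniform gender effects) —
a stand-in for per-site estimates from real data, which are not shipped.

## EWAS pipeline

`run_sitewise` fits one model per CpG site (sites are independent; results
are invariant to site order) and reports estimate, SE, z, p plus
Benjamini–Hochberg and Benjamini–Yekutieli adjusted values from the
in-package step-up implementation (BY = BH × Σ 1/i), cross-checked against
`statsmodels` to 1e−12. Ingestion accepts beta matrices or raw M/U
intensity matrices (b = M/(M+U+a), default a = 100), drops unmatched
samples below a 20% threshold, refuses sites with > 5% missing values, and
clamps beta values to [1e−6, 1 − 1e−6] (counts logged) since the density
lives on the open interval.

## Numerical choices and degenerate inputs

* All density work in log space; the Bessel factor of the bivariate density
  uses the exponentially scaled `ive` so it is finite where the unscaled
  function overflows (needed from ρ ≈ 0.65 upwards at typical intensities).
* The discriminant D = A² − 4ρθb(1−b) is evaluated by the factorization
  (A − 2s)(A + 2s) with A − 2s expanded as
  (√(θb) − √(1−b))² + 2(1 − √ρ)√(θb(1−b)), which avoids catastrophic
  cancellation as ρ → 1 with θ ≈ 1. No further stabilization is applied;
  ρ is capped at 1 − 1e−6 in all evaluations, and only non-negative ρ is
  supported.
* Linear predictors are clipped to ±300 before exponentiation; beta values
  are clamped to [1e−6, 1 − 1e−6] on ingestion.
* Rank-deficient designs raise immediately with the offending columns
  named; factor covariates are dummy-coded against the lexicographically
  first level (the sign of γ depends on this choice).

## Limitations

* Negative intensity correlations are out of scope (ρ ≥ 0).
* The precision/hyperparameters are global per site: no covariate-dependent
  α or ρ, and no spline/additive extensions of the linear predictor.
* Synthetic covariates are independent across columns; power estimates
  conditional on them are close to, but not identical with, estimates
  conditioned on a real cohort design.
* (α̂, ρ̂) are weakly identified in cohort-sized samples (the ridge above):
  their individual sampling error is large even when γ̂ and its standard
  error — the quantities the downstream tests use — are well behaved.
* Pre-processing (normalization, probe filtering, imputation) is assumed
  done; region-level (DMR) inference is not provided.
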