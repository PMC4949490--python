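# Methods

## Model

For individual j (j = 1..J) with group one-hot z_j ∈ {(1,0), (0,1)}
(entity, incremental) and trials t = 1..T:

    S_j ~ Bernoulli(π_j),                π_j = exp(z_j δ) / (1 + exp(z_j δ))
    c_j | S_j = 1 ~ Uniform{1, ..., T−2}
    y_tj | S_j = 0        ~ N(α_1j + β_1j t, σ²)
    y_tj | S_j = 1, t <  c_j ~ N(α_1j + β_1j t, σ²)
    y_tj | S_j = 1, t >= c_j ~ N(α_1j + c_j(β_1j − β_2j) + β_2j t, σ²)

    α_1j ~ N(μ_α, τ²_α)
    β_1j ~ N⁺(z_j μ_β1, τ²_β1)          (positive-truncated normal)
    β_2j ~ N⁻(z_j μ_β2, τ²_β2) if S_j = 1, else β_2j = 0 (point mass)
    δ ~ N(0, c_δ I₂)

The two regression segments share the value α_1j + β_1j c_j at t = c_j, so
every trajectory mean is continuous; the sign constraints make it
monotonically increasing before the cut-point and decreasing after — the
formal definition of a performance spiral adopted here. Cut-points on the
last two trials are excluded so the post-spiral slope always has at least
two observations. c_j = 1 is allowed: the whole series is then post-spiral.

Assumptions worth stating: within-person errors are i.i.d. normal (a
Student-t variant relaxes this; see below); the random intercept and the
random slopes are independent, with no intercept–slope covariance — a
deliberate departure from the usual correlated-random-effects mixed model,
because the covariance is neither identifiable nor meaningful with a single
binary covariate and 12 trials; at most one changepoint per individual; the
trial grid is complete (missing trials are rejected, not imputed).

The baseline latent curve model is the same structure with the spiral
branch removed and an unconstrained slope β_j ~ N(z_j μ_β, τ²_β). The
intercept mean μ_α is shared across groups in both models: before any
feedback has been received there is no reason for the groups to differ,
so only the slope means carry the group structure. (The REML oracle
exposes `shared_intercept=False` for the variant with per-group
intercepts.)

## Inference

One MCMC sweep:

1. **(S_j, c_j)** for each j from its exact discrete full conditional with
   the coefficients integrated out. For each candidate state the marginal
   likelihood is the unconstrained normal–normal evidence times
   P_post(R)/P_prior(R), where R = {β_1 > 0, β_2 < 0}: the prior region
   probability factorizes into univariate normal tails (independent
   priors), and the posterior region probability is a bivariate-normal
   rectangle probability over (β_1, β_2) after marginalizing α_1
   analytically. Rectangle probabilities use Owen's T function
   (accurate to ~1e−14, vectorized); logs are floored at −745 against
   underflow. The unnormalized masses are (1−π_j)·m(no-spiral) and
   (π_j/(T−2))·m(spiral, c); normalization and the categorical draw happen
   in log space (log-sum-exp / Gumbel-max). This exact marginalization was
   chosen over pseudo-prior or reversible-jump schemes because it is
   directly testable against a quadrature oracle.
2. **Coefficients** (α_1j, β_1j, β_2j) by a short Gibbs sub-cycle (3
   scans) of exact univariate conditionals: normal for α_1j,
   positive-truncated normal for β_1j, negative-truncated normal for β_2j
   (pinned at 0 when S_j = 0). Truncated draws use the inverse-CDF method
   through the accurate normal-tail functions, valid out to ~37 standard
   deviations. Sign constraints therefore hold surely in every draw.
3. **δ** by one random-walk Metropolis step per component (the one-hot
   design makes the two components conditionally independent).
4. **Population parameters**: σ², μ_α and τ²_α have exact conjugate
   updates (inverse-gamma / normal — the intercept prior is untruncated,
   so conjugacy survives); μ_β1, μ_β2, τ²_β1, τ²_β2 use random-walk
   Metropolis (log scale for the variances) because the truncated-normal
   normalizing constants Φ(±μ/τ) enter the likelihood of each
   coefficient. Only spirallers contribute to the β_2 hyperparameter
   updates; when a group has no spirallers those conditionals reduce to
   the prior and are sampled directly.

Metropolis proposal scales adapt every 50 iterations during burn-in toward
~30% acceptance (multiplicative Robbins–Monro step, clipped to
[1e−3, 20]) and are frozen afterwards, preserving the correct stationary
distribution for the retained draws. Chains are bit-reproducible from the
seed. Default chain: 50,000 iterations, 10,000 burn-in, thinning 5; the
test suite and acceptance script use shorter chains (800–24,000
iterations) sized so each check's Monte-Carlo error is well below its
assertion tolerance.

The Student-t variant introduces per-observation scales
λ_tj ~ IG(ν/2, ν/2), giving t_ν marginal errors; every likelihood term is
reweighted by 1/λ_tj, and λ has a conjugate inverse-gamma update. The
no-spiral reduction (π ≡ 0, via `fix_pi`), prior-only mode
(likelihood switched off, used for Geweke-style prior recovery), and the
baseline conjugate Gibbs sampler share the same machinery.

## Priors

Hyperpriors follow an empirical-Bayes recipe built from per-individual OLS
line fits (the maximum-likelihood estimates under normal errors): each
population-mean hyperprior is normal, centred at the mean of the
corresponding OLS estimates with sd equal to half their range. For the
changepoint model the pre-spiral slope-mean hyperprior (both group
components) is centred at the mean of the *positive* OLS slopes (fallback:
the absolute overall mean) and the post-spiral one at the negated value,
both with sd half the overall slope range — the baseline recipe does not
determine this split, so it is this package's extension, isolated in
`PriorConfig` for sensitivity analysis. Variance priors are weakly
informative, data-scaled inverse gammas: σ² ~ IG(2.5, b) with prior mean
equal to the pooled OLS residual variance; each τ² ~ IG(2, b) with prior
mean equal to the empirical variance of the corresponding OLS
coefficients. Degenerate cohorts (zero range) floor the hyperprior sd at
1e−3 score units with a warning. δ's prior variance defaults to c_δ = 4,
which makes the induced prior on each π within ~0.04 (Kolmogorov distance)
of uniform; the closed form for the induced prior mass is
Φ(logit(b)/√c_δ) − Φ(logit(a)/√c_δ).

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| c_δ | logit² | 4 | near-uniform prior on each spiral propensity |
| T−2 cut-point states | trials | 10 at T=12 | uniform prior mass 1/(T−2) each |
| chain length / burn-in / thin | iterations | 50k / 10k / 5 | conservative default for J≈28 |
| variance floor | score² | 1e−8 | numerical guard in IG draws |
| log rectangle floor | log units | −745 | smallest exp-representable float |

## Synthetic cohorts

`GeneratorConfig` runs the generative model forward. Defaults emulate a
28-manager, 12-trial management-simulation cohort: two groups of 14,
μ_α = 102 and τ_α = 5 around the task's performance norm of 100,
pre-spiral slope means (2.0, 1.8) with τ_β1 = 1 (score/trial), post-spiral
slope means (−3, −3) with τ_β2 = 1.5, σ = 5, spiral propensities
(0.6, 0.15). Under these settings pooled per-group score means land near
108 (entity) and 112 (incremental) with SDs near 15 and 13, matching the
descriptive scale of the motivating study cohort; the raw study data are
not available, so these values are this package's calibration, recorded in
the config rather than hard-coded.

What the generator does *not* emulate: the task's deterministic
decision-consequence structure (scores are pure trajectory-plus-noise),
serial correlation of within-person errors, individual differences in
error variance, and any relation between the ITA scale responses and the
trajectory parameters beyond the group label. Passing recovery tests on
these cohorts therefore demonstrates correctness of the inference under
the model's own assumptions, not robustness to their violation (the t-error
variant probes one violation).

## Numerical choices and degenerate inputs

* Evidence terms are computed from 2×2/3×3 precision matrices
  (stacked across cut-points and individuals), not T×T covariances.
* The m'D⁻¹m term in the evidence loses float precision when a prior
  variance is pushed below ~1e−8 (cancellation of O(1/τ²) terms); the
  point-mass limit is accurate to ~1e−3 log units at τ² = 1e−16.
* Rectangle probabilities below ~1e−20 are cancellation-limited; such
  states carry no posterior mass and their log weights are floored.
* Median ties in the ITA classification go to the entity (lower) group
  and the tie count is reported — a convention, since the scale's
  original median-split rule for ties is not specified.
* ĉ_j is reported as the posterior median of c_j over spiral draws,
  rounded to the nearest trial, and as 0 when Pr(S_j = 1 | Y) ≤ 0.5: an
  individual who probably did not spiral gets no cut-point.
* The group slope contrast under the spiral model is computed on the
  pre-spiral slope means (μ_E1 − μ_I1) — the model's "learning rate";
  the post-spiral slopes are conditional on spiraling and not comparable
  across groups with different spiral propensities.
* `sensitivity_sweep` refits the full model at every grid point with an
  identical seed policy (simple and honest); importance reweighting of a
  single chain would be faster but couples the grid points.
* All-identical ITA scores, missing trials, T < 4, non-positive variances
  and cut-points outside 1..T−2 are rejected with specific errors.

## Known limitations

* The coefficient refresh after a state change is a short Gibbs sub-cycle
  rather than an exact draw from the truncated trivariate normal; the
  sub-cycle leaves the exact conditional invariant, and the prior-recovery
  and oracle tests bound any practical effect, but draw-for-draw the
  sweep is "partially collapsed with Gibbs refresh", not fully collapsed.
* One changepoint per individual; no intercept–slope covariance; no
  covariates beyond the binary group.
* The REML oracle (statsmodels MixedLM) estimates the baseline model
  only; the changepoint mixture has no frequentist counterpart here —
  that asymmetry is the point of the Bayesian treatment.
* Bayesian and REML baseline estimates differ by a small systematic
  amount (order 0.01 on slope means for J = 28, T = 12) attributable to
  the variance priors; the acceptance check compares the routes at a
  fraction of the estimator standard errors, where they agree.
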