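# spiralmix

Hierarchical Bayesian changepoint-mixture modelling of individual-level
performance dynamics on multi-trial tasks.

## The problem

When people learn a complex task over repeated trials, theories of
motivation predict qualitatively different *within-person* trajectories:
some individuals keep improving, while others — particularly those who
believe ability is fixed ("entity theorists" on the implicit-theory-of-
ability (ITA) scale, versus "incremental theorists") — may *spiral*: improve
up to some trial, then decline steadily after a setback. Group-level
statistics cannot tell these apart; the question is inherently about each
individual's trajectory, estimated from only a dozen observations.

`spiralmix` models a cohort of J individuals observed over T trials
(performance scores on a ~100-centred percentage scale) with a latent curve
model extended by a per-individual changepoint mixture:

* **No spiral** (S_j = 0): y_tj = α_1j + β_1j·t + ε_tj, with β_1j > 0 and
  β_2j pinned at 0 by a point-mass prior.
* **Spiral at cut-point c_j** (S_j = 1, c_j ∈ {1..T−2}):
  y_tj = α_1j + β_1j·t before c_j and α_1j + c_j(β_1j − β_2j) + β_2j·t from
  t ≥ c_j — continuous at the cut-point, with β_1j ~ N⁺(z_j μ_β1, τ²_β1)
  positive-truncated and β_2j ~ N⁻(z_j μ_β2, τ²_β2) negative-truncated.
* **Spiral propensity**: S_j ~ Bernoulli(π_j) with logistic group model
  π_j = exp(z_j δ)/(1 + exp(z_j δ)), δ ~ N(0, c_δ I₂), and a uniform
  cut-point prior Pr(c_j = t | S_j = 1) = 1/(T−2).

Each individual ranges over 11 candidate models (at T = 12); inference
averages over all of them exactly. The data-augmentation MCMC draws
(S_j, c_j) from its **exact** 11-state full conditional by integrating the
regression coefficients out analytically (a normal–normal marginal times a
bivariate-normal rectangle probability for the sign constraints), then
refreshes coefficients through truncated-normal Gibbs conditionals, δ by
random-walk Metropolis, and the population means/variances by conjugate or
Metropolis-within-Gibbs updates. A Student-t error variant (inverse-gamma
scale mixture) is included for robustness checks, as are a conjugate Gibbs
sampler and a REML oracle for the no-changepoint baseline model, empirical-
Bayes hyperprior construction from per-individual OLS fits, and a synthetic
cohort generator with known ground truth (the study-scale default: 28
individuals, two groups of 14, 12 trials).

## Worked example

```bash
spiralmix simulate --seed 3 --out cohort.csv --truth truth.csv
spiralmix fit-baseline --data cohort.csv --iters 2000 --burn 500 --seed 1 --out base.csv
spiralmix fit-spiral   --data cohort.csv --iters 1500 --burn 500 --thin 1 --seed 1 --out draws.csv
```

prints

```
wrote 28x12 cohort to cohort.csv
Pr(mu_E < mu_I | Y) = 0.999
group mean spiral probabilities: {'entity': 0.8589285714285714, 'incremental': 0.05035714285714286}
Pr(pi_E > pi_I | Y) = 1.000
```

Reading the numbers: under the baseline straight-line model the posterior
probability that the entity group's mean learning rate μ_E is below the
incremental group's μ_I is 0.999 on this synthetic cohort. Under the spiral
model, the average posterior spiral probability is 0.86 in the entity group
versus 0.05 in the incremental group, and the posterior probability that the
entity spiral propensity exceeds the incremental one, Pr(π_E > π_I | Y), is
essentially 1 — this cohort was generated with true propensities
(0.6, 0.15), so the model recovers the built-in group difference.

The same analysis is available as a library:

```python
from spiralmix import (study_like_fixture, empirical_bayes_priors,
                       MCMCConfig, run_spiral_mcmc, spiral_table)

cohort, truth = study_like_fixture(seed=3)
priors = empirical_bayes_priors(cohort)
draws = run_spiral_mcmc(cohort, priors, MCMCConfig(n_iter=20_000,
                                                   burn_in=5_000, seed=1))
report = spiral_table(draws)       # per-individual Pr(S_j=1|Y) and c_hat_j
```

`sensitivity_sweep` refits the model over a grid of δ prior variances
c_δ and tracks Pr(π_E > π_I | Y); `prior_induced_pi(c_delta, (a, b))` gives
the closed-form prior mass that the propensity lies in [a, b] (for
c_δ = 0.01, the prior is ~95% certain that π ∈ [0.45, 0.55], which is the
amount of prior scepticism needed to flatten a strong group difference).

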