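"""Changepoint-mixture ("spiral") model and its data-augmentation MCMC.

Model, per individual j with group one-hot z_j and trials t = 1..T:

* latent spiral indicator S_j ~ Bernoulli(pi_j), with logistic group
  propensity pi_j = exp(z_j delta) / (1 + exp(z_j delta)) and prior
  delta ~ N(0, c_delta I_2);
* cut-point c_j | S_j = 1 uniform on {1..T-2} (a spiral may not begin on
  the last two trials);
* y_tj ~ N(alpha_1j + beta_1j t, sigma^2) before the cut-point and
  N(alpha_1j + c_j (beta_1j - beta_2j) + beta_2j t, sigma^2) from t >= c_j,
  so the mean is continuous at the cut-point;
* alpha_1j ~ N(mu_alpha, tau_alpha^2);
  beta_1j ~ N+(z_j mu_beta1, tau_beta1^2) (positive-truncated);
  beta_2j ~ N-(z_j mu_beta2, tau_beta2^2) when S_j = 1 and is exactly 0
  (a point mass) when S_j = 0.

Each individual therefore ranges over 11 models (no spiral, or a spiral
starting at one of T-2 = 10 trials when T = 12), and the sampler
averages over all of them exactly: the (S_j, c_j) update integrates the
regression coefficients out analytically — an unconstrained
normal-normal marginal times the ratio of posterior to prior probability
of the sign-constraint region, the posterior term being a
bivariate-normal rectangle probability over (beta_1, beta_2) after
marginalizing alpha_1 — so (S_j, c_j) is drawn from its exact 11-state
full conditional.  Coefficients are then refreshed by a short Gibbs
sub-cycle of exact univariate conditionals (truncated normals for the
slopes), delta by random-walk Metropolis per group, and the
hyperparameters by conjugate updates where conjugacy holds (sigma^2,
mu_alpha, tau_alpha^2) and random-walk Metropolis where the
truncated-normal normalizers break it (mu_beta1, mu_beta2, tau_beta1^2,
tau_beta2^2).

A Student-t error variant uses per-observation inverse-gamma latent
scales (the usual scale mixture), which enters every likelihood term as
an observation weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_ndtr, logsumexp

from ._stats import LOG_FLOOR, VAR_FLOOR, log_bvn_rect, sample_truncnorm
from .data_model import CohortData
from .priors import PriorConfig

__all__ = [
    "SpiralState", "GroupHyperparameters", "MCMCConfig", "PosteriorDraws",
    "piecewise_design", "log_marginal", "state_log_probs",
    "sample_spiral_state", "sample_coefficients", "update_delta",
    "update_hypers", "run_spiral_mcmc", "run_spiral_mcmc_t",
]

LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpiralState:
    """Per-individual latent state: spiral indicator and cut-point.

    ``c`` is defined only when ``S = 1`` and must lie in 1..T-2; it is
    stored as 0 when ``S = 0``.
    """

    S: int
    c: int = 0

    def __post_init__(self) -> None:
        if self.S not in (0, 1):
            raise ValueError("S must be 0 or 1")
        if self.S == 1 and self.c < 1:
            raise ValueError("a spiral state needs a cut-point >= 1")
        if self.S == 0 and self.c != 0:
            raise ValueError("no-spiral state carries no cut-point")


@dataclass
class GroupHyperparameters:
    """Population-level parameters of the spiral model.

    Group-indexed vectors are ordered (entity, incremental).  ``pi`` is
    derived from ``delta`` through the logistic function.
    """

    mu_alpha: float
    tau_alpha2: float
    mu_beta1: np.ndarray      # (2,)
    tau_beta12: float
    mu_beta2: np.ndarray      # (2,)
    tau_beta22: float
    sigma2: float
    delta: np.ndarray         # (2,)

    def __post_init__(self) -> None:
        self.mu_beta1 = np.asarray(self.mu_beta1, dtype=float)
        self.mu_beta2 = np.asarray(self.mu_beta2, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        for v, name in [(self.tau_alpha2, "tau_alpha2"),
                        (self.tau_beta12, "tau_beta12"),
                        (self.tau_beta22, "tau_beta22"),
                        (self.sigma2, "sigma2")]:
            if v <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def pi(self) -> np.ndarray:
        """Per-group spiral probabilities (entity, incremental)."""
        return expit(self.delta)

    def copy(self) -> "GroupHyperparameters":
        return GroupHyperparameters(
            mu_alpha=self.mu_alpha, tau_alpha2=self.tau_alpha2,
            mu_beta1=self.mu_beta1.copy(), tau_beta12=self.tau_beta12,
            mu_beta2=self.mu_beta2.copy(), tau_beta22=self.tau_beta22,
            sigma2=self.sigma2, delta=self.delta.copy())


@dataclass
class MCMCConfig:
    """Chain settings.  ``seed`` is mandatory for reproducibility."""

    n_iter: int = 50_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0
    n_coef_scans: int = 3
    prior_only: bool = False
    fix_pi: tuple[float, float] | None = None  # bypasses the delta update

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained draws of all parameters and latent states.

    Per-individual arrays have shape (n_draws, J); ``c`` is 0 wherever
    ``S`` is 0.  ``acceptance`` maps each Metropolis component to its
    post-burn-in acceptance rate.
    """

    mu_alpha: np.ndarray
    tau_alpha2: np.ndarray
    mu_beta1: np.ndarray      # (n, 2)
    tau_beta12: np.ndarray
    mu_beta2: np.ndarray      # (n, 2)
    tau_beta22: np.ndarray
    sigma2: np.ndarray
    delta: np.ndarray         # (n, 2)
    S: np.ndarray             # (n, J)
    c: np.ndarray             # (n, J)
    alpha1: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    individual_ids: list = field(default_factory=list)
    groups: list = field(default_factory=list)
    n_trials: int = 0
    seed: int | None = None
    n_iter: int = 0
    burn_in: int = 0
    thin: int = 1
    acceptance: dict = field(default_factory=dict)

    @property
    def pi(self) -> np.ndarray:
        """Draws of (pi_E, pi_I), shape (n, 2)."""
        return expit(self.delta)

    @property
    def n_draws(self) -> int:
        return self.S.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "mu_alpha": self.mu_alpha, "tau_alpha2": self.tau_alpha2,
            "mu_beta1_E": self.mu_beta1[:, 0], "mu_beta1_I": self.mu_beta1[:, 1],
            "mu_beta2_E": self.mu_beta2[:, 0], "mu_beta2_I": self.mu_beta2[:, 1],
            "tau_beta12": self.tau_beta12, "tau_beta22": self.tau_beta22,
            "sigma2": self.sigma2,
            "delta_E": self.delta[:, 0], "delta_I": self.delta[:, 1],
        }
        for k, ind in enumerate(self.individual_ids):
            cols[f"S_{ind}"] = self.S[:, k]
            cols[f"c_{ind}"] = self.c[:, k]
            cols[f"alpha1_{ind}"] = self.alpha1[:, k]
            cols[f"beta1_{ind}"] = self.beta1[:, k]
            cols[f"beta2_{ind}"] = self.beta2[:, k]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# design and exact coefficient marginalization
# ---------------------------------------------------------------------------

def piecewise_design(c: int, T: int) -> np.ndarray:
    """T x 3 design for (alpha_1, beta_1, beta_2) with cut-point c.

    Row t is (1, t, 0) before the cut-point and (1, c, t - c) from t >= c,
    i.e. columns (1, min(t, c), max(t - c, 0)); the implied mean is
    continuous at t = c.
    """
    if not 1 <= c <= T - 2:
        raise ValueError(f"cut-point {c} outside admissible range 1..{T - 2}")
    t = np.arange(1, T + 1, dtype=float)
    return np.column_stack([np.ones(T), np.minimum(t, c),
                            np.maximum(t - c, 0.0)])


def _evidence(y, X, m, d, sigma2, w):
    """Unconstrained normal-normal log evidence plus posterior moments.

    y | theta ~ N(X theta, sigma^2 / w elementwise), theta ~ N(m, diag(d)).
    Returns (log evidence, posterior mean, posterior covariance).
    """
    Xw = X * w[:, None]
    A = np.diag(1.0 / d) + X.T @ Xw / sigma2
    b = Xw.T @ y / sigma2 + m / d
    cov = np.linalg.inv(A)
    mu = cov @ b
    _, logdet_A = np.linalg.slogdet(A)
    quad = (y * w) @ y / sigma2 + np.sum(m**2 / d) - b @ mu
    log_m = (-0.5 * np.sum(LOG2PI + np.log(sigma2 / w))
             - 0.5 * (np.sum(np.log(d)) + logdet_A) - 0.5 * quad)
    return log_m, mu, cov


def log_marginal(y: np.ndarray, state: SpiralState,
                 hypers: GroupHyperparameters, group: int,
                 weights: np.ndarray | None = None) -> float:
    """Log marginal likelihood of one model state, coefficients integrated out.

    For a spiral state the exact integral is the unconstrained
    normal-normal marginal times P_post(beta_1 > 0, beta_2 < 0) /
    P_prior(beta_1 > 0, beta_2 < 0): the posterior term is a
    bivariate-normal rectangle probability (alpha_1 marginalized out) and
    the prior term a product of univariate tail probabilities (the slope
    priors are independent).  For the no-spiral state beta_2 is pinned at
    0 by its point-mass prior and the correction is univariate in beta_1.
    Rectangle probabilities are evaluated in log space and floored at
    exp(-745) against underflow.
    """
    y = np.asarray(y, dtype=float)
    T = y.size
    w = np.ones(T) if weights is None else np.asarray(weights, dtype=float)
    if state.S == 1:
        X = piecewise_design(state.c, T)
        m = np.array([hypers.mu_alpha, hypers.mu_beta1[group],
                      hypers.mu_beta2[group]])
        d = np.array([hypers.tau_alpha2, hypers.tau_beta12, hypers.tau_beta22])
        log_m, mu, cov = _evidence(y, X, m, d, hypers.sigma2, w)
        log_post = log_bvn_rect(mu[1], mu[2], cov[1, 1], cov[2, 2], cov[1, 2])
        log_prior = (log_ndtr(m[1] / np.sqrt(d[1]))
                     + log_ndtr(-m[2] / np.sqrt(d[2])))
    else:
        t = np.arange(1, T + 1, dtype=float)
        X = np.column_stack([np.ones(T), t])
        m = np.array([hypers.mu_alpha, hypers.mu_beta1[group]])
        d = np.array([hypers.tau_alpha2, hypers.tau_beta12])
        log_m, mu, cov = _evidence(y, X, m, d, hypers.sigma2, w)
        log_post = max(log_ndtr(mu[1] / np.sqrt(cov[1, 1])), LOG_FLOOR)
        log_prior = log_ndtr(m[1] / np.sqrt(d[1]))
    return float(log_m + log_post - log_prior)


def state_log_probs(y: np.ndarray, hypers: GroupHyperparameters, group: int,
                    weights: np.ndarray | None = None) -> np.ndarray:
    """Normalized log probabilities of the T-1 model states for one series.

    Entry 0 is the no-spiral state; entry c (1-based) the spiral state
    with cut-point c.  The unnormalized masses are (1 - pi) m(no-spiral)
    and pi / (T - 2) * m(spiral, c); normalization by log-sum-exp.
    """
    T = y.size
    n_cuts = T - 2
    pi = float(hypers.pi[group])
    logw = np.empty(n_cuts + 1)
    with np.errstate(divide="ignore"):
        logw[0] = np.log1p(-pi) + log_marginal(
            y, SpiralState(0), hypers, group, weights)
        log_pi = np.log(pi) if pi > 0 else -np.inf
    for c in range(1, n_cuts + 1):
        logw[c] = log_pi - np.log(n_cuts) + log_marginal(
            y, SpiralState(1, c), hypers, group, weights)
    norm = logsumexp(logw)
    if not np.isfinite(norm):
        raise RuntimeError("all model-state masses vanished; "
                           "check prior/likelihood configuration")
    return logw - norm


def sample_spiral_state(y: np.ndarray, hypers: GroupHyperparameters,
                        group: int, rng: np.random.Generator,
                        weights: np.ndarray | None = None) -> SpiralState:
    """Draw (S_j, c_j) from its exact discrete full conditional."""
    logp = state_log_probs(y, hypers, group, weights)
    k = int(np.argmax(logp + rng.gumbel(size=logp.size)))
    return SpiralState(0) if k == 0 else SpiralState(1, k)


# ---------------------------------------------------------------------------
# coefficient Gibbs sub-cycle
# ---------------------------------------------------------------------------

def _coef_scan(y, x2, x3, S, g, hypers, rng, alpha, beta1, beta2,
               w, n_scans, prior_only=False):
    """Vectorized Gibbs sub-cycle over all individuals; returns new coefs."""
    J = y.shape[0]
    sigma2 = hypers.sigma2
    ta2, tb12, tb22 = hypers.tau_alpha2, hypers.tau_beta12, hypers.tau_beta22
    mb1 = hypers.mu_beta1[g]
    mb2 = hypers.mu_beta2[g]
    if prior_only:
        alpha = rng.normal(hypers.mu_alpha, np.sqrt(ta2), size=J)
        beta1 = sample_truncnorm(mb1, np.sqrt(tb12), rng, lower=0.0)
        beta2 = np.where(
            S == 1, sample_truncnorm(mb2, np.sqrt(tb22), rng, upper=0.0), 0.0)
        return alpha, beta1, beta2
    sw = w.sum(axis=1)
    swx2 = (w * x2 * x2).sum(axis=1)
    swx3 = (w * x3 * x3).sum(axis=1)
    for _ in range(n_scans):
        r = y - beta1[:, None] * x2 - beta2[:, None] * x3
        prec = sw / sigma2 + 1.0 / ta2
        mean = ((w * r).sum(axis=1) / sigma2 + hypers.mu_alpha / ta2) / prec
        alpha = mean + rng.standard_normal(J) / np.sqrt(prec)

        r = y - alpha[:, None] - beta2[:, None] * x3
        prec = swx2 / sigma2 + 1.0 / tb12
        mean = ((w * x2 * r).sum(axis=1) / sigma2 + mb1 / tb12) / prec
        beta1 = sample_truncnorm(mean, 1.0 / np.sqrt(prec), rng, lower=0.0)

        r = y - alpha[:, None] - beta1[:, None] * x2
        prec = swx3 / sigma2 + 1.0 / tb22
        mean = ((w * x3 * r).sum(axis=1) / sigma2 + mb2 / tb22) / prec
        draw = sample_truncnorm(mean, 1.0 / np.sqrt(prec), rng, upper=0.0)
        beta2 = np.where(S == 1, draw, 0.0)
    return alpha, beta1, beta2


def sample_coefficients(y: np.ndarray, state: SpiralState,
                        hypers: GroupHyperparameters, group: int,
                        rng: np.random.Generator,
                        current: tuple[float, float, float] | None = None,
                        n_scans: int = 3,
                        weights: np.ndarray | None = None
                        ) -> tuple[float, float, float]:
    """Draw (alpha_1j, beta_1j, beta_2j) given one individual's (S_j, c_j).

    A Gibbs sub-cycle of exact univariate conditionals: normal for
    alpha_1, positive-truncated normal for beta_1, negative-truncated
    normal for beta_2 (or exactly 0 under the no-spiral point mass).
    Sign constraints hold surely in the output.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    T = y.shape[1]
    t = np.arange(1, T + 1, dtype=float)
    c_eff = state.c if state.S == 1 else T
    x2 = np.minimum(t, c_eff)[None, :]
    x3 = (np.maximum(t - c_eff, 0.0) * state.S)[None, :]
    w = np.ones_like(y) if weights is None else np.atleast_2d(weights)
    if current is None:
        current = (hypers.mu_alpha, max(hypers.mu_beta1[group], 0.1),
                   min(hypers.mu_beta2[group], -0.1))
    a, b1, b2 = (np.array([v], dtype=float) for v in current)
    a, b1, b2 = _coef_scan(
        y, x2, x3, np.array([state.S]), np.array([group]), hypers, rng,
        a, b1, b2, w, n_scans)
    return float(a[0]), float(b1[0]), float(b2[0])


# ---------------------------------------------------------------------------
# delta and hyperparameter updates
# ---------------------------------------------------------------------------

def update_delta(S: np.ndarray, group_idx: np.ndarray, c_delta: float,
                 rng: np.random.Generator, delta: np.ndarray,
                 prop_sd: np.ndarray | None = None, n_steps: int = 1
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk Metropolis update of the logistic coefficients delta.

    With a one-hot group design the two components are conditionally
    independent: each sees a Bernoulli likelihood with k_g spirallers out
    of n_g members and the N(0, c_delta) prior.  A group with no members
    leaves that component sampled from its prior conditional (the random
    walk then targets the prior).  Returns (delta, acceptance counts).
    """
    delta = np.asarray(delta, dtype=float).copy()
    prop_sd = np.full(2, 0.8) if prop_sd is None else np.asarray(prop_sd)
    accepts = np.zeros(2)

    def logpost(d, k, n):
        return -d * d / (2.0 * c_delta) + k * d - n * np.logaddexp(0.0, d)

    for gi in range(2):
        mask = group_idx == gi
        n_g = int(mask.sum())
        k_g = int(S[mask].sum())
        for _ in range(n_steps):
            prop = delta[gi] + prop_sd[gi] * rng.standard_normal()
            log_r = logpost(prop, k_g, n_g) - logpost(delta[gi], k_g, n_g)
            if np.log(rng.uniform()) < log_r:
                delta[gi] = prop
                accepts[gi] += 1
    return delta, accepts


def _log_ig(x, a, b):
    return -(a + 1.0) * np.log(x) - b / x


def update_hypers(alpha1: np.ndarray, beta1: np.ndarray, beta2: np.ndarray,
                  S: np.ndarray, group_idx: np.ndarray,
                  priors: PriorConfig, hypers: GroupHyperparameters,
                  rng: np.random.Generator,
                  resid_ss: float | None = None, n_obs: int = 0,
                  prop_sd: dict | None = None) -> dict:
    """One sweep of population-parameter updates (in place on ``hypers``).

    sigma^2, mu_alpha and tau_alpha^2 have exact conjugate conditionals
    (the intercept prior is untruncated).  The slope means and scales
    carry truncated-normal normalizers, so (mu_beta1, mu_beta2,
    tau_beta1^2, tau_beta2^2) use random-walk Metropolis (log scale for
    the variances).  Only spirallers contribute to the beta_2 updates; a
    group with no spirallers reduces those conditionals to the prior,
    which is then sampled directly.  ``resid_ss=None`` means no
    likelihood (prior-only run): sigma^2 is drawn from its prior.
    Returns per-component acceptance indicators.
    """
    J = alpha1.size
    acc = {}
    prop_sd = prop_sd or {}

    # sigma^2 — conjugate inverse gamma
    a_s, b_s = priors.sigma2
    if resid_ss is None:
        hypers.sigma2 = b_s / rng.gamma(a_s)
    else:
        hypers.sigma2 = max(
            (b_s + 0.5 * resid_ss) / rng.gamma(a_s + 0.5 * n_obs), VAR_FLOOR)

    # mu_alpha — conjugate normal
    ma0, sa0 = priors.mu_alpha
    prec = J / hypers.tau_alpha2 + 1.0 / sa0**2
    mean = (alpha1.sum() / hypers.tau_alpha2 + ma0 / sa0**2) / prec
    hypers.mu_alpha = rng.normal(mean, 1.0 / np.sqrt(prec))

    # tau_alpha^2 — conjugate inverse gamma
    a_t, b_t = priors.tau_alpha2
    ss = np.sum((alpha1 - hypers.mu_alpha) ** 2)
    hypers.tau_alpha2 = max(
        (b_t + 0.5 * ss) / rng.gamma(a_t + 0.5 * J), VAR_FLOOR)

    # mu_beta1 components — MH with the positive-truncation normalizer
    c1, s1 = priors.mu_beta1
    tb1 = np.sqrt(hypers.tau_beta12)
    for gi in range(2):
        b = beta1[group_idx == gi]
        cur = hypers.mu_beta1[gi]
        sd = prop_sd.get(f"mu_beta1_{gi}", 0.5)

        def lp(m, b=b):
            return (-(m - c1) ** 2 / (2 * s1**2)
                    - np.sum((b - m) ** 2) / (2 * hypers.tau_beta12)
                    - b.size * log_ndtr(m / tb1))

        prop = cur + sd * rng.standard_normal()
        ok = np.log(rng.uniform()) < lp(prop) - lp(cur)
        if ok:
            hypers.mu_beta1[gi] = prop
        acc[f"mu_beta1_{gi}"] = float(ok)

    # mu_beta2 components — spirallers only; no spirallers -> prior draw
    c2, s2 = priors.mu_beta2
    tb2 = np.sqrt(hypers.tau_beta22)
    for gi in range(2):
        b = beta2[(group_idx == gi) & (S == 1)]
        if b.size == 0:
            hypers.mu_beta2[gi] = rng.normal(c2, s2)
            continue
        cur = hypers.mu_beta2[gi]
        sd = prop_sd.get(f"mu_beta2_{gi}", 0.5)

        def lp(m, b=b):
            return (-(m - c2) ** 2 / (2 * s2**2)
                    - np.sum((b - m) ** 2) / (2 * hypers.tau_beta22)
                    - b.size * log_ndtr(-m / tb2))

        prop = cur + sd * rng.standard_normal()
        ok = np.log(rng.uniform()) < lp(prop) - lp(cur)
        if ok:
            hypers.mu_beta2[gi] = prop
        acc[f"mu_beta2_{gi}"] = float(ok)

    # tau_beta1^2 — MH on the log scale, all individuals contribute
    a1, b1p = priors.tau_beta12
    dev1 = beta1 - hypers.mu_beta1[group_idx]

    def lp_t1(logv):
        v = np.exp(logv)
        return (_log_ig(v, a1, b1p)
                - 0.5 * J * logv - np.sum(dev1**2) / (2 * v)
                - np.sum(log_ndtr(hypers.mu_beta1[group_idx] / np.sqrt(v)))
                + logv)  # Jacobian of the log transform

    cur = np.log(hypers.tau_beta12)
    sd = prop_sd.get("tau_beta12", 0.5)
    prop = cur + sd * rng.standard_normal()
    ok = np.log(rng.uniform()) < lp_t1(prop) - lp_t1(cur)
    if ok:
        hypers.tau_beta12 = max(np.exp(prop), VAR_FLOOR)
    acc["tau_beta12"] = float(ok)

    # tau_beta2^2 — spirallers only
    a2, b2p = priors.tau_beta22
    sp = S == 1
    if not np.any(sp):
        hypers.tau_beta22 = max(b2p / rng.gamma(a2), VAR_FLOOR)
    else:
        dev2 = beta2[sp] - hypers.mu_beta2[group_idx[sp]]
        n_sp = int(sp.sum())

        def lp_t2(logv):
            v = np.exp(logv)
            return (_log_ig(v, a2, b2p)
                    - 0.5 * n_sp * logv - np.sum(dev2**2) / (2 * v)
                    - np.sum(log_ndtr(-hypers.mu_beta2[group_idx[sp]]
                                      / np.sqrt(v)))
                    + logv)

        cur = np.log(hypers.tau_beta22)
        sd = prop_sd.get("tau_beta22", 0.5)
        prop = cur + sd * rng.standard_normal()
        ok = np.log(rng.uniform()) < lp_t2(prop) - lp_t2(cur)
        if ok:
            hypers.tau_beta22 = max(np.exp(prop), VAR_FLOOR)
        acc["tau_beta22"] = float(ok)
    return acc


# ---------------------------------------------------------------------------
# the full sampler
# ---------------------------------------------------------------------------

class _StateSampler:
    """Batched exact (S_j, c_j) updates for a whole cohort.

    Precomputes the per-cut-point designs and data cross-products so one
    sweep costs a handful of small stacked linear-algebra calls.
    """

    def __init__(self, cohort: CohortData):
        self.y = cohort.scores
        self.J, self.T = self.y.shape
        self.n_cuts = self.T - 2
        t = np.arange(1, self.T + 1, dtype=float)
        self.X = np.stack([piecewise_design(c, self.T)
                           for c in range(1, self.n_cuts + 1)])  # (C, T, 3)
        self.X0 = np.column_stack([np.ones(self.T), t])          # (T, 2)
        self.g = cohort.group_indicator()

    def log_weights(self, hypers: GroupHyperparameters,
                    w: np.ndarray | None = None) -> np.ndarray:
        """Unnormalized log masses of the 1 + (T-2) states, shape (C+1, J)."""
        y, J, C = self.y, self.J, self.n_cuts
        sigma2 = hypers.sigma2
        g = self.g
        w = np.ones_like(y) if w is None else w

        d3 = np.array([hypers.tau_alpha2, hypers.tau_beta12, hypers.tau_beta22])
        m3 = np.stack([np.full(J, hypers.mu_alpha),
                       hypers.mu_beta1[g], hypers.mu_beta2[g]])   # (3, J)
        d2 = d3[:2]
        m2 = m3[:2]

        # spiral states: A (C, J, 3, 3) = diag(1/d) + X' W_j X / sigma^2
        Xw = np.einsum("cti,jt->cjti", self.X, w)
        XtWX = np.einsum("cjti,ctk->cjik", Xw, self.X)
        A = XtWX / sigma2 + np.diag(1.0 / d3)
        XtWy = np.einsum("cjti,jt->cji", Xw, y)
        b = XtWy / sigma2 + (m3 / d3[:, None]).T[None, :, :]      # (C, J, 3)
        cov = np.linalg.inv(A)
        mu = np.einsum("cjik,cjk->cji", cov, b)
        _, logdet_A = np.linalg.slogdet(A)
        ywy = np.einsum("jt,jt,jt->j", y, w, y)
        base = (-0.5 * (LOG2PI + np.log(sigma2)) * self.T
                + 0.5 * np.log(w).sum(axis=1))                    # (J,)
        quad = (ywy / sigma2 + np.sum(m3**2 / d3[:, None], axis=0)
                - np.einsum("cji,cji->cj", b, mu))
        log_m = (base[None, :] - 0.5 * (np.sum(np.log(d3)) + logdet_A)
                 - 0.5 * quad)
        log_rect = log_bvn_rect(mu[:, :, 1], mu[:, :, 2],
                                cov[:, :, 1, 1], cov[:, :, 2, 2],
                                cov[:, :, 1, 2])
        log_prior_region = (log_ndtr(m3[1] / np.sqrt(d3[1]))
                            + log_ndtr(-m3[2] / np.sqrt(d3[2])))  # (J,)
        log_spiral = log_m + log_rect - log_prior_region[None, :]

        # no-spiral state (2-dim, beta_2 pinned at 0)
        X0w = np.einsum("ti,jt->jti", self.X0, w)
        A0 = np.einsum("jti,tk->jik", X0w, self.X0) / sigma2 + np.diag(1.0 / d2)
        b0 = np.einsum("jti,jt->ji", X0w, y) / sigma2 + (m2 / d2[:, None]).T
        cov0 = np.linalg.inv(A0)
        mu0 = np.einsum("jik,jk->ji", cov0, b0)
        _, logdet_A0 = np.linalg.slogdet(A0)
        quad0 = (ywy / sigma2 + np.sum(m2**2 / d2[:, None], axis=0)
                 - np.einsum("ji,ji->j", b0, mu0))
        log_m0 = base - 0.5 * (np.sum(np.log(d2)) + logdet_A0) - 0.5 * quad0
        log_pos0 = np.maximum(
            log_ndtr(mu0[:, 1] / np.sqrt(cov0[:, 1, 1])), LOG_FLOOR)
        log_nospiral = log_m0 + log_pos0 - log_ndtr(m2[1] / np.sqrt(d2[1]))

        pi = hypers.pi[g]
        with np.errstate(divide="ignore"):
            logw = np.vstack([
                np.log1p(-pi) + log_nospiral,
                np.where(pi[None, :] > 0, np.log(pi[None, :]), -np.inf)
                - np.log(C) + log_spiral,
            ])
        return logw

    def prior_log_weights(self, hypers: GroupHyperparameters) -> np.ndarray:
        """State log masses with the likelihood switched off (prior only)."""
        pi = hypers.pi[self.g]
        with np.errstate(divide="ignore"):
            logw = np.vstack([
                np.log1p(-pi),
                np.broadcast_to(
                    np.where(pi > 0, np.log(pi), -np.inf) - np.log(self.n_cuts),
                    (self.n_cuts, self.J)),
            ])
        return logw

    def draw(self, logw: np.ndarray, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray]:
        """Gumbel-max categorical draw per individual; returns (S, c)."""
        norm = logsumexp(logw, axis=0)
        if not np.all(np.isfinite(norm)):
            raise RuntimeError("all model-state masses vanished for some "
                               "individual; model misconfiguration")
        k = np.argmax(logw + rng.gumbel(size=logw.shape), axis=0)
        S = (k > 0).astype(int)
        c = np.where(S == 1, k, 0)
        return S, c


class _Adapter:
    """Robbins-Monro style proposal-scale adaptation during burn-in."""

    def __init__(self, names, target=0.3, batch=50):
        self.sd = {n: 0.5 for n in names}
        self.sd.update({n: 0.8 for n in names if n.startswith("delta")})
        self.target = target
        self.batch = batch
        self.counts = {n: [0, 0] for n in names}

    def record(self, name, accepted):
        acc, tot = self.counts[name]
        self.counts[name] = [acc + accepted, tot + 1]

    def maybe_adapt(self):
        for n, (acc, tot) in self.counts.items():
            if tot >= self.batch:
                rate = acc / tot
                self.sd[n] *= np.exp(rate - self.target)
                self.sd[n] = float(np.clip(self.sd[n], 1e-3, 20.0))
                self.counts[n] = [0, 0]


def run_spiral_mcmc(cohort: CohortData, priors: PriorConfig,
                    config: MCMCConfig,
                    error_df: float | None = None) -> PosteriorDraws:
    """Full data-augmentation MCMC for the spiral changepoint model.

    One sweep per iteration: for each individual the exact
    coefficient-marginalized (S_j, c_j) draw, then the coefficient Gibbs
    sub-cycle; then delta (random-walk Metropolis per group); then the
    population parameters.  Metropolis proposal scales adapt toward ~30%
    acceptance during burn-in and are frozen afterwards.  Bit-reproducible
    from ``config.seed``.

    ``error_df`` switches on Student-t errors with that many degrees of
    freedom via per-observation latent scales; ``None`` means normal
    errors.
    """
    rng = np.random.default_rng(config.seed)
    J, T = cohort.n_individuals, cohort.n_trials
    y = cohort.scores
    g = cohort.group_indicator()
    t = np.arange(1, T + 1, dtype=float)
    sampler = _StateSampler(cohort)

    # initial state: prior centres, no spirallers
    hypers = GroupHyperparameters(
        mu_alpha=priors.mu_alpha[0],
        tau_alpha2=priors.tau_alpha2[1] / max(priors.tau_alpha2[0] - 1, 0.5),
        mu_beta1=np.full(2, priors.mu_beta1[0]),
        tau_beta12=priors.tau_beta12[1] / max(priors.tau_beta12[0] - 1, 0.5),
        mu_beta2=np.full(2, priors.mu_beta2[0]),
        tau_beta22=priors.tau_beta22[1] / max(priors.tau_beta22[0] - 1, 0.5),
        sigma2=priors.sigma2[1] / max(priors.sigma2[0] - 1, 0.5),
        delta=np.zeros(2),
    )
    if config.fix_pi is not None:
        eps = 1e-12
        p = np.clip(np.asarray(config.fix_pi, dtype=float), eps, 1 - eps)
        hypers.delta = np.log(p / (1 - p))
    S = np.zeros(J, dtype=int)
    c = np.zeros(J, dtype=int)
    alpha1 = np.full(J, hypers.mu_alpha)
    beta1 = np.maximum(hypers.mu_beta1[g], 0.1)
    beta2 = np.zeros(J)
    lam = np.ones((J, T))  # latent t scales; stays 1 for normal errors

    mh_names = ["delta_0", "delta_1", "mu_beta1_0", "mu_beta1_1",
                "mu_beta2_0", "mu_beta2_1", "tau_beta12", "tau_beta22"]
    adapter = _Adapter(mh_names)
    accept_post = {n: [0, 0] for n in mh_names}

    n_keep = (config.n_iter - config.burn_in) // config.thin
    keep = {
        "mu_alpha": np.empty(n_keep), "tau_alpha2": np.empty(n_keep),
        "mu_beta1": np.empty((n_keep, 2)), "tau_beta12": np.empty(n_keep),
        "mu_beta2": np.empty((n_keep, 2)), "tau_beta22": np.empty(n_keep),
        "sigma2": np.empty(n_keep), "delta": np.empty((n_keep, 2)),
        "S": np.empty((n_keep, J), dtype=np.int8),
        "c": np.empty((n_keep, J), dtype=np.int16),
        "alpha1": np.empty((n_keep, J)), "beta1": np.empty((n_keep, J)),
        "beta2": np.empty((n_keep, J)),
    }
    kept = 0

    for it in range(config.n_iter):
        w = 1.0 / lam if error_df is not None else None

        # 1. exact 11-state (S_j, c_j) draw, coefficients marginalized
        logw = (sampler.prior_log_weights(hypers) if config.prior_only
                else sampler.log_weights(hypers, w))
        S, c = sampler.draw(logw, rng)

        # 2. coefficient sub-cycle
        c_eff = np.where(S == 1, c, T)
        x2 = np.minimum(t[None, :], c_eff[:, None])
        x3 = np.maximum(t[None, :] - c_eff[:, None], 0.0)
        w_arr = np.ones((J, T)) if w is None else w
        alpha1, beta1, beta2 = _coef_scan(
            y, x2, x3, S, g, hypers, rng, alpha1, beta1, beta2, w_arr,
            config.n_coef_scans, prior_only=config.prior_only)

        resid = y - alpha1[:, None] - beta1[:, None] * x2 - beta2[:, None] * x3

        # 3. latent t scales
        if error_df is not None and not config.prior_only:
            lam = ((error_df + resid**2 / hypers.sigma2)
                   / (2.0 * rng.gamma((error_df + 1.0) / 2.0, size=(J, T))))
            w_arr = 1.0 / lam

        # 4. delta (unless pi is pinned)
        if config.fix_pi is None:
            sds = np.array([adapter.sd["delta_0"], adapter.sd["delta_1"]])
            hypers.delta, acc_d = update_delta(
                S, g, priors.c_delta, rng, hypers.delta, prop_sd=sds)
            for gi in range(2):
                name = f"delta_{gi}"
                adapter.record(name, acc_d[gi])
                if it >= config.burn_in:
                    accept_post[name][0] += acc_d[gi]
                    accept_post[name][1] += 1

        # 5. population parameters
        if config.prior_only:
            resid_ss, n_obs = None, 0
        else:
            resid_ss = float(np.sum(w_arr * resid**2))
            n_obs = J * T
        acc_h = update_hypers(alpha1, beta1, beta2, S, g, priors, hypers, rng,
                              resid_ss=resid_ss, n_obs=n_obs,
                              prop_sd=adapter.sd)
        for name, ok in acc_h.items():
            adapter.record(name, ok)
            if it >= config.burn_in:
                accept_post[name][0] += ok
                accept_post[name][1] += 1

        if it < config.burn_in:
            adapter.maybe_adapt()

        if not (np.isfinite(hypers.sigma2) and np.all(np.isfinite(alpha1))
                and np.all(np.isfinite(beta1))):
            raise RuntimeError(
                f"divergent chain at iteration {it}: "
                f"sigma2={hypers.sigma2}, mu_beta1={hypers.mu_beta1}")

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            keep["mu_alpha"][kept] = hypers.mu_alpha
            keep["tau_alpha2"][kept] = hypers.tau_alpha2
            keep["mu_beta1"][kept] = hypers.mu_beta1
            keep["tau_beta12"][kept] = hypers.tau_beta12
            keep["mu_beta2"][kept] = hypers.mu_beta2
            keep["tau_beta22"][kept] = hypers.tau_beta22
            keep["sigma2"][kept] = hypers.sigma2
            keep["delta"][kept] = hypers.delta
            keep["S"][kept] = S
            keep["c"][kept] = c
            keep["alpha1"][kept] = alpha1
            keep["beta1"][kept] = beta1
            keep["beta2"][kept] = beta2
            kept += 1

    acceptance = {n: (a / t if t else np.nan)
                  for n, (a, t) in accept_post.items()}
    return PosteriorDraws(
        mu_alpha=keep["mu_alpha"], tau_alpha2=keep["tau_alpha2"],
        mu_beta1=keep["mu_beta1"], tau_beta12=keep["tau_beta12"],
        mu_beta2=keep["mu_beta2"], tau_beta22=keep["tau_beta22"],
        sigma2=keep["sigma2"], delta=keep["delta"],
        S=keep["S"], c=keep["c"], alpha1=keep["alpha1"],
        beta1=keep["beta1"], beta2=keep["beta2"],
        individual_ids=list(cohort.individual_ids),
        groups=list(cohort.groups), n_trials=T,
        seed=config.seed, n_iter=config.n_iter, burn_in=config.burn_in,
        thin=config.thin, acceptance=acceptance,
    )


def run_spiral_mcmc_t(cohort: CohortData, priors: PriorConfig,
                      config: MCMCConfig, nu: float) -> PosteriorDraws:
    """Robustness variant with Student-t_nu errors (nu > 2).

    Identical sampler with per-observation latent inverse-gamma scale
    variables; every likelihood term is reweighted by their inverses.
    """
    if nu <= 2:
        raise ValueError("nu > 2 required")
    return run_spiral_mcmc(cohort, priors, config, error_df=nu)
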