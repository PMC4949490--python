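"""Baseline latent curve model: straight-line trajectories, no changepoint.

Each individual j has their own line y_tj = alpha_j + beta_j * t + eps_tj,
eps ~ N(0, sigma^2), with alpha_j ~ N(mu_alpha, tau_alpha^2) shared across
groups and beta_j ~ N(mu_g(j), tau_beta^2) where the slope mean mu_g is
group-specific (mu_E for entity, mu_I for incremental theorists).  The
random intercept and random slope are independent by construction — this
is deliberately not the usual correlated-random-effects mixed model.

Two fitting routes are provided:

* :func:`gibbs_lcm` — fully conjugate Gibbs sampler (normal updates for
  coefficients and means, inverse-gamma updates for variances).
* :func:`fit_lcm_ml` — REML fit of the equivalent linear mixed model
  (random intercept plus an independent random-slope variance component),
  used as a frequentist cross-check of the Bayesian posterior means.

The group difference in average learning rate is summarised by
:func:`slope_contrast` on the posterior of mu_E - mu_I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from ._stats import VAR_FLOOR
from .data_model import CohortData
from .priors import PriorConfig

__all__ = ["BaselineDraws", "LcmMlFit", "gibbs_lcm", "fit_lcm_ml",
           "slope_contrast", "ContrastSummary"]


@dataclass
class BaselineDraws:
    """Retained Gibbs draws for the baseline model (one row per draw)."""

    mu_alpha: np.ndarray
    mu_E: np.ndarray
    mu_I: np.ndarray
    tau_alpha2: np.ndarray
    tau_beta2: np.ndarray
    sigma2: np.ndarray
    alpha: np.ndarray  # (n_draws, J)
    beta: np.ndarray   # (n_draws, J)
    individual_ids: list = field(default_factory=list)
    seed: int | None = None
    n_iter: int = 0
    burn_in: int = 0
    thin: int = 1

    def to_dataframe(self) -> pd.DataFrame:
        """Flat columnar table, per-individual columns suffixed by id."""
        cols = {
            "mu_alpha": self.mu_alpha, "mu_E": self.mu_E, "mu_I": self.mu_I,
            "tau_alpha2": self.tau_alpha2, "tau_beta2": self.tau_beta2,
            "sigma2": self.sigma2,
        }
        for k, ind in enumerate(self.individual_ids):
            cols[f"alpha_{ind}"] = self.alpha[:, k]
            cols[f"beta_{ind}"] = self.beta[:, k]
        return pd.DataFrame(cols)


def _draw_invgamma(rng, shape, scale):
    return scale / rng.gamma(shape)


def gibbs_lcm(cohort: CohortData, priors: PriorConfig,
              n_iter: int = 20_000, burn_in: int = 5_000,
              thin: int = 1, seed: int | None = None,
              prior_only: bool = False) -> BaselineDraws:
    """Conjugate Gibbs sampler for the baseline latent curve model.

    With ``prior_only=True`` the likelihood is switched off and the chain
    targets the joint prior — a successive-substitution check that every
    full conditional is coded correctly (each parameter's retained draws
    should then reproduce its prior moments).
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng(seed)
    J, T = cohort.n_individuals, cohort.n_trials
    y = cohort.scores
    t = cohort.trials.astype(float)
    g = cohort.group_indicator()  # 0 entity, 1 incremental
    group_masks = [g == 0, g == 1]

    ma0, sa0 = priors.mu_alpha
    mb0, sb0 = priors.mu_beta
    a_sig, b_sig = priors.sigma2
    a_ta, b_ta = priors.tau_alpha2
    a_tb, b_tb = priors.tau_beta2_baseline

    # state
    mu_alpha, mu_beta = ma0, np.array([mb0, mb0])
    tau_a2 = b_ta / max(a_ta - 1, 0.5)
    tau_b2 = b_tb / max(a_tb - 1, 0.5)
    sigma2 = b_sig / max(a_sig - 1, 0.5)
    alpha = np.full(J, mu_alpha)
    beta = mu_beta[g].astype(float).copy()

    sum_t, sum_t2 = t.sum(), (t**2).sum()
    n_keep = (n_iter - burn_in) // thin
    out = {k: np.empty(n_keep) for k in
           ("mu_alpha", "mu_E", "mu_I", "tau_alpha2", "tau_beta2", "sigma2")}
    out_alpha = np.empty((n_keep, J))
    out_beta = np.empty((n_keep, J))
    kept = 0

    for it in range(n_iter):
        # (alpha_j, beta_j) joint bivariate normal conditional
        if prior_only:
            alpha = rng.normal(mu_alpha, np.sqrt(tau_a2), size=J)
            beta = rng.normal(mu_beta[g], np.sqrt(tau_b2), size=J)
        else:
            p11 = T / sigma2 + 1.0 / tau_a2
            p12 = sum_t / sigma2
            p22 = sum_t2 / sigma2 + 1.0 / tau_b2
            det = p11 * p22 - p12 * p12
            if det <= 0 or not np.isfinite(det):
                raise RuntimeError(
                    f"non-positive-definite conditional at iteration {it}")
            b1 = y.sum(axis=1) / sigma2 + mu_alpha / tau_a2
            b2 = y @ t / sigma2 + mu_beta[g] / tau_b2
            m_a = (p22 * b1 - p12 * b2) / det
            m_b = (p11 * b2 - p12 * b1) / det
            # Cholesky of the 2x2 covariance (= inverse precision)
            s_a = np.sqrt(p22 / det)
            z1, z2 = rng.standard_normal(J), rng.standard_normal(J)
            alpha = m_a + s_a * z1
            # beta | alpha: normal with precision p22, mean shifted by alpha
            cond_m = m_b - (p12 / p22) * (alpha - m_a)
            beta = cond_m + z2 / np.sqrt(p22)

        # mu_alpha
        prec = J / tau_a2 + 1.0 / sa0**2
        mean = (alpha.sum() / tau_a2 + ma0 / sa0**2) / prec
        mu_alpha = rng.normal(mean, 1.0 / np.sqrt(prec))

        # mu_E, mu_I
        for gi, mask in enumerate(group_masks):
            n_g = int(mask.sum())
            prec = n_g / tau_b2 + 1.0 / sb0**2
            mean = (beta[mask].sum() / tau_b2 + mb0 / sb0**2) / prec
            mu_beta[gi] = rng.normal(mean, 1.0 / np.sqrt(prec))

        # variances
        tau_a2 = max(_draw_invgamma(
            rng, a_ta + J / 2.0, b_ta + 0.5 * np.sum((alpha - mu_alpha) ** 2)),
            VAR_FLOOR)
        tau_b2 = max(_draw_invgamma(
            rng, a_tb + J / 2.0, b_tb + 0.5 * np.sum((beta - mu_beta[g]) ** 2)),
            VAR_FLOOR)
        if prior_only:
            sigma2 = _draw_invgamma(rng, a_sig, b_sig)
        else:
            resid = y - alpha[:, None] - beta[:, None] * t
            sigma2 = max(_draw_invgamma(
                rng, a_sig + J * T / 2.0, b_sig + 0.5 * np.sum(resid**2)),
                VAR_FLOOR)

        if it >= burn_in and (it - burn_in) % thin == 0:
            out["mu_alpha"][kept] = mu_alpha
            out["mu_E"][kept] = mu_beta[0]
            out["mu_I"][kept] = mu_beta[1]
            out["tau_alpha2"][kept] = tau_a2
            out["tau_beta2"][kept] = tau_b2
            out["sigma2"][kept] = sigma2
            out_alpha[kept] = alpha
            out_beta[kept] = beta
            kept += 1

    return BaselineDraws(
        mu_alpha=out["mu_alpha"], mu_E=out["mu_E"], mu_I=out["mu_I"],
        tau_alpha2=out["tau_alpha2"], tau_beta2=out["tau_beta2"],
        sigma2=out["sigma2"], alpha=out_alpha, beta=out_beta,
        individual_ids=list(cohort.individual_ids),
        seed=seed, n_iter=n_iter, burn_in=burn_in, thin=thin,
    )


@dataclass
class LcmMlFit:
    """REML point estimates and standard errors for the baseline model."""

    mu_alpha: dict          # {"shared": est} or {"entity": ..., "incremental": ...}
    mu_alpha_se: dict
    mu_E: float
    mu_I: float
    mu_E_se: float
    mu_I_se: float
    tau_alpha2: float
    tau_beta2: float
    sigma2: float
    converged: bool


def fit_lcm_ml(cohort: CohortData, shared_intercept: bool = True) -> LcmMlFit:
    """REML fit of the baseline model as a linear mixed model.

    Random intercept and an *independent* random slope (a variance
    component, no intercept-slope covariance), fixed effects: one shared
    intercept (or per-group with ``shared_intercept=False``) and a
    group-specific trial slope.
    """
    if cohort.n_individuals < 2:
        raise ValueError("REML fit needs at least 2 individuals")
    df = cohort.to_frame()
    fixed = ("score ~ 1 + C(group):trial" if shared_intercept
             else "score ~ 0 + C(group) + C(group):trial")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(fixed, df, groups=df["individual"],
                            re_formula="1", vc_formula={"trial": "0 + trial"})
        try:
            res = model.fit(reml=True, method=["lbfgs", "powell"])
        except Exception as exc:  # noqa: BLE001 - surface optimizer failure
            raise RuntimeError(f"REML optimization failed: {exc}") from exc
    if not res.converged:
        raise RuntimeError(
            f"REML did not converge; optimizer summary:\n{res.summary()}")

    params, bse = res.params, res.bse
    slope_E = "C(group)[entity]:trial"
    slope_I = "C(group)[incremental]:trial"
    if shared_intercept:
        mu_alpha = {"shared": float(params["Intercept"])}
        mu_alpha_se = {"shared": float(bse["Intercept"])}
    else:
        mu_alpha = {"entity": float(params["C(group)[entity]"]),
                    "incremental": float(params["C(group)[incremental]"])}
        mu_alpha_se = {"entity": float(bse["C(group)[entity]"]),
                       "incremental": float(bse["C(group)[incremental]"])}
    return LcmMlFit(
        mu_alpha=mu_alpha, mu_alpha_se=mu_alpha_se,
        mu_E=float(params[slope_E]), mu_I=float(params[slope_I]),
        mu_E_se=float(bse[slope_E]), mu_I_se=float(bse[slope_I]),
        tau_alpha2=float(np.asarray(res.cov_re)[0, 0]),
        tau_beta2=float(res.vcomp[0]),
        sigma2=float(res.scale),
        converged=bool(res.converged),
    )


@dataclass
class ContrastSummary:
    """Posterior summary of a draw-wise difference (e.g. mu_E - mu_I)."""

    diffs: np.ndarray
    frac_below_zero: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.diffs.mean())


def slope_contrast(draws: BaselineDraws, bins: int = 40) -> ContrastSummary:
    """Posterior of the slope-mean difference mu_E - mu_I.

    ``frac_below_zero`` estimates Pr(mu_E < mu_I | Y): the probability
    that entity theorists learn more slowly on average.
    """
    diffs = draws.mu_E - draws.mu_I
    span = (None if np.ptp(diffs) > 1e-9
            else (diffs[0] - 0.5, diffs[0] + 0.5))  # degenerate: single value
    counts, edges = np.histogram(diffs, bins=bins, range=span)
    return ContrastSummary(
        diffs=diffs,
        frac_below_zero=float(np.mean(diffs < 0)),
        hist_counts=counts, hist_edges=edges,
    )
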