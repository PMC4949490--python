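"""Empirical-Bayes hyperprior construction and fixed prior constants.

The hyperpriors on the population means (mu_alpha and the slope means)
are normal, centred at the average of per-individual ordinary
least-squares estimates with standard deviation equal to half the range
of those estimates.  OLS line fits are the maximum-likelihood estimates
of the individual regression coefficients under normal errors, so this
is the classical empirical-Bayes recipe: pick the prior family, let
frequentist point estimates fix its constants.

For the changepoint model the pre-spiral slope-mean hyperprior (both
group components) is centred at the mean of the *positive* OLS slopes
(falling back to the absolute overall mean when no slope is positive)
and the post-spiral slope-mean hyperprior at the negated value, each
with sd equal to half the OLS-slope range.  Variance hyperpriors are
weakly informative inverse gammas scaled to the OLS fits: sigma^2 ~
IG(2.5, b) with b set so the prior mean equals the pooled OLS residual
variance, and each tau^2 ~ IG(2, b) with prior mean equal to the
empirical variance of the corresponding OLS coefficients.  All of these
constants live in :class:`PriorConfig` and can be overridden for
sensitivity analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .data_model import CohortData

SD_FLOOR = 1e-3  # score units; guards degenerate (zero-range) cohorts

__all__ = ["PriorConfig", "per_individual_ols", "empirical_bayes_priors",
           "SD_FLOOR"]


@dataclass
class PriorConfig:
    """Fully resolved prior constants for the baseline and spiral models.

    Normal hyperpriors are (center, sd) pairs; inverse-gamma priors are
    (shape, scale) pairs with mean scale/(shape-1).  ``c_delta`` is the
    prior variance of each logistic spiral-propensity coefficient,
    delta ~ N(0, c_delta * I_2); the default 4 induces an approximately
    uniform prior on each group's spiral probability.  The cut-point
    prior is uniform, mass 1/(T-2) per admissible trial.
    """

    mu_alpha: tuple[float, float] = (100.0, 10.0)
    mu_beta: tuple[float, float] = (0.0, 2.0)      # baseline (unconstrained) slope mean
    mu_beta1: tuple[float, float] = (2.0, 2.0)     # pre-spiral slope mean, both groups
    mu_beta2: tuple[float, float] = (-2.0, 2.0)    # post-spiral slope mean, both groups
    sigma2: tuple[float, float] = (2.5, 37.5)
    tau_alpha2: tuple[float, float] = (2.0, 25.0)
    tau_beta2_baseline: tuple[float, float] = (2.0, 1.0)
    tau_beta12: tuple[float, float] = (2.0, 1.0)
    tau_beta22: tuple[float, float] = (2.0, 1.0)
    c_delta: float = 4.0

    def __post_init__(self) -> None:
        for name in ("mu_alpha", "mu_beta", "mu_beta1", "mu_beta2"):
            c, s = getattr(self, name)
            if s <= 0:
                raise ValueError(f"{name} hyperprior sd must be positive")
        for name in ("sigma2", "tau_alpha2", "tau_beta2_baseline",
                     "tau_beta12", "tau_beta22"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} IG parameters must be positive")
        if self.c_delta <= 0:
            raise ValueError("c_delta must be positive")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorConfig":
        return cls(**{k: (tuple(v) if isinstance(v, list) else v)
                      for k, v in d.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "PriorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def replace(self, **kw) -> "PriorConfig":
        d = asdict(self)
        d.update(kw)
        return PriorConfig(**d)


def per_individual_ols(cohort: CohortData) -> np.ndarray:
    """OLS line fit of score on trial for each individual.

    Returns an array of shape (J, 2): column 0 intercepts, column 1
    slopes.  These are the per-individual maximum-likelihood estimates
    under normal errors.
    """
    T = cohort.n_trials
    if T < 2:
        raise ValueError("need at least 2 trials for a line fit")
    t = cohort.trials.astype(float)
    X = np.column_stack([np.ones(T), t])
    coef, *_ = np.linalg.lstsq(X, cohort.scores.T, rcond=None)
    return coef.T  # (J, 2)


def _half_range(x: np.ndarray) -> float:
    hr = float(np.ptp(x)) / 2.0
    if hr < SD_FLOOR:
        warnings.warn(
            "zero (or near-zero) range of OLS estimates; hyperprior sd "
            f"floored at {SD_FLOOR}", stacklevel=3)
        hr = SD_FLOOR
    return hr


def empirical_bayes_priors(cohort: CohortData,
                           sigma2_shape: float = 2.5,
                           tau_shape: float = 2.0,
                           c_delta: float = 4.0) -> PriorConfig:
    """Build a :class:`PriorConfig` from per-individual OLS fits.

    See the module docstring for the recipe.  The result is invariant to
    the ordering of individuals in the cohort.
    """
    if cohort.n_individuals < 2:
        raise ValueError("empirical Bayes needs at least 2 individuals")
    coefs = per_individual_ols(cohort)
    intercepts, slopes = coefs[:, 0], coefs[:, 1]

    mu_alpha = (float(intercepts.mean()), _half_range(intercepts))
    slope_sd = _half_range(slopes)
    mu_beta = (float(slopes.mean()), slope_sd)

    pos = slopes[slopes > 0]
    beta1_center = float(pos.mean()) if pos.size else abs(float(slopes.mean()))
    mu_beta1 = (beta1_center, slope_sd)
    mu_beta2 = (-beta1_center, slope_sd)

    # pooled OLS residual variance scales the sigma^2 prior
    t = cohort.trials.astype(float)
    fitted = intercepts[:, None] + slopes[:, None] * t
    resid = cohort.scores - fitted
    dof = max(cohort.n_individuals * (cohort.n_trials - 2), 1)
    s2 = float(np.sum(resid**2)) / dof
    s2 = max(s2, SD_FLOOR**2)
    sigma2 = (sigma2_shape, (sigma2_shape - 1.0) * s2)

    var_a = max(float(np.var(intercepts, ddof=1)), SD_FLOOR**2)
    var_b = max(float(np.var(slopes, ddof=1)), SD_FLOOR**2)
    tau_alpha2 = (tau_shape, (tau_shape - 1.0) * var_a)
    tau_b = (tau_shape, (tau_shape - 1.0) * var_b)

    return PriorConfig(
        mu_alpha=mu_alpha, mu_beta=mu_beta,
        mu_beta1=mu_beta1, mu_beta2=mu_beta2,
        sigma2=sigma2, tau_alpha2=tau_alpha2,
        tau_beta2_baseline=tau_b, tau_beta12=tau_b, tau_beta22=tau_b,
        c_delta=c_delta,
    )
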