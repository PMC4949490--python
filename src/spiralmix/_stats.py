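"""Numerical primitives shared across the samplers.

Log-space floors: rectangle probabilities that underflow double precision
are floored at exp(LOG_FLOOR); variances are floored at VAR_FLOOR.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri, owens_t

LOG_FLOOR = -745.0  # smallest log representable as exp() > 0 in float64
VAR_FLOOR = 1e-8

__all__ = [
    "LOG_FLOOR",
    "VAR_FLOOR",
    "sample_truncnorm",
    "bvn_upper_orthant",
    "log_bvn_rect",
]


def sample_truncnorm(mean, sd, rng, lower=None, upper=None):
    """Draw from one-sided truncated normals, vectorized over mean/sd.

    Exactly one of ``lower``/``upper`` may be given (both None = plain
    normal).  Uses the inverse-CDF method through the normal tail
    (``ndtri`` is accurate for arguments down to ~1e-308), which covers
    standardized bounds out to ~37 sd; beyond that the draw collapses to
    the bound, which is within float spacing of the true quantile.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    u = rng.uniform(size=np.broadcast(mean, sd).shape)
    # guard against u == 0 exactly, which would map to the untruncated tail
    u = np.clip(u, 1e-16, 1.0 - 1e-16)
    if lower is not None and upper is not None:
        raise NotImplementedError("two-sided truncation not needed here")
    if lower is not None:
        a = (np.asarray(lower, dtype=float) - mean) / sd
        # P(Z >= a) = ndtr(-a); quantile via the accurate small-argument tail
        z = -ndtri(u * ndtr(-a))
        z = np.maximum(z, a)
        return mean + sd * z
    if upper is not None:
        b = (np.asarray(upper, dtype=float) - mean) / sd
        z = ndtri(u * ndtr(b))
        z = np.minimum(z, b)
        return mean + sd * z
    return mean + sd * rng.standard_normal(size=u.shape)


def _phi2(h, k, rho):
    """Standard bivariate normal P(X <= h, Y <= k), vectorized (Owen 1956)."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.clip(np.asarray(rho, dtype=float), -1 + 1e-12, 1 - 1e-12)
    denom = np.sqrt(1.0 - rho**2)
    # a-arguments; at h == 0 take the one-sided limit via +/- inf
    with np.errstate(divide="ignore", invalid="ignore"):
        ah = (k - rho * h) / (h * denom)
        ak = (h - rho * k) / (k * denom)
    with np.errstate(invalid="ignore"):
        ah = np.where(h == 0.0,
                      np.sign(k) * np.inf * np.where(k == 0, np.nan, 1), ah)
        ak = np.where(k == 0.0,
                      np.sign(h) * np.inf * np.where(h == 0, np.nan, 1), ak)
    # owens_t(h, +/-inf) limits: T(h, inf) = (1 - ndtr(|h|)) / 2, odd in a
    t_h = np.where(
        np.isinf(ah), np.sign(ah) * (1.0 - ndtr(np.abs(h))) / 2.0, owens_t(h, np.where(np.isfinite(ah), ah, 0.0))
    )
    t_k = np.where(
        np.isinf(ak), np.sign(ak) * (1.0 - ndtr(np.abs(k))) / 2.0, owens_t(k, np.where(np.isfinite(ak), ak, 0.0))
    )
    beta = np.where((h * k > 0) | ((h * k == 0) & (h + k >= 0)), 0.0, 0.5)
    val = 0.5 * (ndtr(h) + ndtr(k)) - t_h - t_k - beta
    # both arguments zero: closed form 1/4 + asin(rho)/(2 pi)
    both_zero = (h == 0.0) & (k == 0.0)
    if np.any(both_zero):
        val = np.where(both_zero, 0.25 + np.arcsin(rho) / (2 * np.pi), val)
    return np.clip(val, 0.0, 1.0)


def bvn_upper_orthant(mu1, mu2, var1, var2, cov12):
    """P(X1 > 0, X2 < 0) for (X1, X2) bivariate normal, vectorized.

    This is the sign-constraint region for (beta1, beta2): a positive
    pre-changepoint slope and a negative post-changepoint slope.
    """
    s1 = np.sqrt(var1)
    s2 = np.sqrt(var2)
    rho = cov12 / (s1 * s2)
    # P(X1 > 0, X2 < 0) = P(-X1 <= 0, X2 <= 0) with corr(-X1, X2) = -rho
    return _phi2(np.asarray(mu1) / s1, -np.asarray(mu2) / s2, -rho)


def log_bvn_rect(mu1, mu2, var1, var2, cov12):
    """log P(X1 > 0, X2 < 0), floored at LOG_FLOOR against underflow."""
    p = bvn_upper_orthant(mu1, mu2, var1, var2, cov12)
    with np.errstate(divide="ignore"):
        return np.maximum(np.log(p), LOG_FLOOR)


def log_pos_prob(mean, sd):
    """log P(X > 0) for X ~ N(mean, sd^2), accurate in both tails."""
    return log_ndtr(np.asarray(mean, dtype=float) / np.asarray(sd, dtype=float))


def log_neg_prob(mean, sd):
    """log P(X < 0) for X ~ N(mean, sd^2)."""
    return log_ndtr(-np.asarray(mean, dtype=float) / np.asarray(sd, dtype=float))
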