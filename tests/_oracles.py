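"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own evidence computations: the
marginal likelihood oracle integrates the slope priors on a dense 2-D
grid (intercept integrated in closed form through the one-dimensional
conjugate identity), and the truncated-posterior oracle uses plain
rejection sampling.
"""

import numpy as np
from scipy.integrate import simpson
from scipy.stats import norm


def quad_log_marginal_spiral(y, c, hypers, group, n_grid=601, width=10.0):
    """2-D quadrature over (beta1 > 0, beta2 < 0), alpha integrated exactly."""
    y = np.asarray(y, dtype=float)
    T = y.size
    t = np.arange(1, T + 1)
    x2 = np.minimum(t, c).astype(float)
    x3 = np.maximum(t - c, 0).astype(float)
    s2 = hypers.sigma2
    ta2, mu_a = hypers.tau_alpha2, hypers.mu_alpha
    m1, sd1 = hypers.mu_beta1[group], np.sqrt(hypers.tau_beta12)
    m2, sd2 = hypers.mu_beta2[group], np.sqrt(hypers.tau_beta22)
    b1g = np.linspace(1e-9, max(m1 + width * sd1, width * sd1), n_grid)
    b2g = np.linspace(min(m2 - width * sd2, -width * sd2), -1e-9, n_grid)
    lp1 = norm.logpdf(b1g, m1, sd1) - norm.logcdf(m1 / sd1)
    lp2 = norm.logpdf(b2g, m2, sd2) - norm.logcdf(-m2 / sd2)
    prec = T / s2 + 1.0 / ta2
    vals = np.empty((n_grid, n_grid))
    for i, b1 in enumerate(b1g):
        r = y[None, :] - b1 * x2[None, :] - b2g[:, None] * x3[None, :]
        quad = ((r**2).sum(1) / s2 + mu_a**2 / ta2
                - (r.sum(1) / s2 + mu_a / ta2) ** 2 / prec)
        logm = (-0.5 * T * np.log(2 * np.pi * s2) - 0.5 * np.log(ta2 * prec)
                - 0.5 * quad)
        vals[i] = np.exp(logm + lp1[i] + lp2)
    return float(np.log(simpson(simpson(vals, x=b2g, axis=1), x=b1g)))


def quad_log_marginal_nospiral(y, hypers, group, n_grid=4001, width=10.0):
    """1-D quadrature over beta1 > 0 (beta2 pinned at 0)."""
    y = np.asarray(y, dtype=float)
    T = y.size
    t = np.arange(1, T + 1, dtype=float)
    s2 = hypers.sigma2
    ta2, mu_a = hypers.tau_alpha2, hypers.mu_alpha
    m1, sd1 = hypers.mu_beta1[group], np.sqrt(hypers.tau_beta12)
    b1g = np.linspace(1e-9, max(m1 + width * sd1, width * sd1), n_grid)
    lp1 = norm.logpdf(b1g, m1, sd1) - norm.logcdf(m1 / sd1)
    prec = T / s2 + 1.0 / ta2
    r = y[None, :] - b1g[:, None] * t[None, :]
    quad = ((r**2).sum(1) / s2 + mu_a**2 / ta2
            - (r.sum(1) / s2 + mu_a / ta2) ** 2 / prec)
    logm = -0.5 * T * np.log(2 * np.pi * s2) - 0.5 * np.log(ta2 * prec) - 0.5 * quad
    return float(np.log(simpson(np.exp(logm + lp1), x=b1g)))


def rejection_truncated_posterior(y, c, hypers, group, rng, n_keep=4000):
    """Exact draws from p(alpha, b1, b2 | y, S=1, c) by rejection.

    Samples the unconstrained trivariate normal posterior and keeps
    draws with b1 > 0, b2 < 0.
    """
    y = np.asarray(y, dtype=float)
    T = y.size
    t = np.arange(1, T + 1)
    X = np.column_stack([np.ones(T), np.minimum(t, c), np.maximum(t - c, 0)])
    m = np.array([hypers.mu_alpha, hypers.mu_beta1[group],
                  hypers.mu_beta2[group]])
    d = np.array([hypers.tau_alpha2, hypers.tau_beta12, hypers.tau_beta22])
    A = np.diag(1.0 / d) + X.T @ X / hypers.sigma2
    cov = np.linalg.inv(A)
    mu = cov @ (X.T @ y / hypers.sigma2 + m / d)
    L = np.linalg.cholesky(cov)
    out = []
    while sum(len(o) for o in out) < n_keep:
        z = rng.standard_normal((20000, 3))
        draws = mu + z @ L.T
        keep = draws[(draws[:, 1] > 0) & (draws[:, 2] < 0)]
        out.append(keep)
    return np.vstack(out)[:n_keep]
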