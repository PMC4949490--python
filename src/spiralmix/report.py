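"""Posterior summaries, group contrasts and prior-sensitivity analytics.

Per-individual reports follow the convention used for cohort summary
tables: the spiral probability is the retained-draw mean of S_j; the
cut-point estimate c_hat_j is the posterior median of c_j conditional on
S_j = 1, reported as 0 when Pr(S_j = 1 | Y) <= 0.5 (an individual who
probably did not spiral gets no cut-point).  Histogram analogues of the
posterior-contrast figures are emitted as bin-edge/count tables so they
are testable artifacts; plotting is left to the caller.

The module also carries the closed-form prior calculation for the
spiral-propensity scale: with delta ~ N(0, c_delta), the induced prior
probability that pi = logistic(delta) lies in [a, b] is
Phi(logit(b) / sqrt(c_delta)) - Phi(logit(a) / sqrt(c_delta)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import logit, ndtr

from .data_model import CohortData
from .priors import PriorConfig
from .spiral_mcmc import MCMCConfig, PosteriorDraws, run_spiral_mcmc

__all__ = [
    "SpiralReport", "spiral_table", "summarize_spiral_probabilities",
    "load_example_spiral_table", "pi_contrast", "fitted_trajectory",
    "TrajectorySummary", "sensitivity_sweep", "prior_induced_pi",
    "prior_pi_cdf",
]


@dataclass
class SpiralReport:
    """Individual-level spiral summaries plus group aggregates.

    ``table`` has one row per individual: individual, group, pr_spiral,
    c_hat.  ``group_means`` averages pr_spiral within each group;
    ``n_above_half`` / ``n_not_above_half`` count individuals on either
    side of the 0.5 threshold per group.  The contrast fields are filled
    only when the report is built from posterior draws.
    """

    table: pd.DataFrame
    group_means: dict
    n_above_half: dict
    n_not_above_half: dict
    frac_mu_E1_below_mu_I1: float | None = None
    frac_pi_E_above_pi_I: float | None = None


def summarize_spiral_probabilities(table: pd.DataFrame) -> SpiralReport:
    """Group aggregates from a per-individual table.

    ``table`` needs columns individual, group, pr_spiral and (optionally)
    c_hat.  Group averages are plain means of the members' probabilities;
    the threshold counts split each group at pr_spiral > 0.5.
    """
    required = {"individual", "group", "pr_spiral"}
    if missing := required - set(table.columns):
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    group_means, above, not_above = {}, {}, {}
    for grp, sub in table.groupby("group"):
        group_means[grp] = float(sub["pr_spiral"].mean())
        above[grp] = int((sub["pr_spiral"] > 0.5).sum())
        not_above[grp] = int((sub["pr_spiral"] <= 0.5).sum())
    return SpiralReport(table=table.copy(), group_means=group_means,
                        n_above_half=above, n_not_above_half=not_above)


def spiral_table(draws: PosteriorDraws,
                 labels: list[str] | None = None) -> SpiralReport:
    """Per-individual spiral probabilities and cut-point medians from draws.

    Pr(S_j = 1 | Y) is the retained-draw mean of S_j.  c_hat_j is the
    posterior median of c_j over draws with S_j = 1, rounded to the
    nearest trial, and reported as 0 when Pr(S_j = 1 | Y) <= 0.5.
    """
    groups = labels if labels is not None else draws.groups
    pr = draws.S.mean(axis=0)
    c_hat = np.zeros(len(pr))
    for k in range(len(pr)):
        if pr[k] > 0.5:
            cs = draws.c[draws.S[:, k] == 1, k]
            c_hat[k] = int(round(float(np.median(cs))))
    table = pd.DataFrame({
        "individual": draws.individual_ids,
        "group": groups,
        "pr_spiral": pr,
        "c_hat": c_hat.astype(int),
    })
    rep = summarize_spiral_probabilities(table)
    pi = draws.pi
    rep.frac_mu_E1_below_mu_I1 = float(
        np.mean(draws.mu_beta1[:, 0] < draws.mu_beta1[:, 1]))
    rep.frac_pi_E_above_pi_I = float(np.mean(pi[:, 0] > pi[:, 1]))
    return rep


def load_example_spiral_table() -> pd.DataFrame:
    """The packaged worked-example summary table for a 28-person cohort.

    Columns individual, group, pr_spiral, c_hat; used to exercise the
    summary arithmetic of :func:`summarize_spiral_probabilities` on
    realistic published-scale numbers.
    """
    ref = resources.files("spiralmix").joinpath("data/example_spiral_table.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


@dataclass
class ContrastTable:
    """Draw-wise contrast with its exceedance fraction and histogram."""

    diffs: np.ndarray
    frac_positive: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def pi_contrast(draws: PosteriorDraws, bins: int = 40) -> ContrastTable:
    """Posterior of pi_E - pi_I (spiral-propensity difference).

    Each delta draw is pushed through the logistic function;
    ``frac_positive`` estimates Pr(pi_E > pi_I | Y).
    """
    pi = draws.pi
    diffs = pi[:, 0] - pi[:, 1]
    span = (None if np.ptp(diffs) > 1e-9
            else (diffs[0] - 0.5, diffs[0] + 0.5))
    counts, edges = np.histogram(diffs, bins=bins, range=span)
    return ContrastTable(diffs=diffs,
                         frac_positive=float(np.mean(diffs > 0)),
                         hist_counts=counts, hist_edges=edges)


@dataclass
class TrajectorySummary:
    """Model-averaged fitted trajectory for one individual."""

    trials: np.ndarray
    mean: np.ndarray            # E(y_hat_tj), averaged over draws
    pr_spiral: float
    cut_pmf: pd.Series          # Pr(c_j = t | Y), over admissible t


def fitted_trajectory(draws: PosteriorDraws, individual) -> TrajectorySummary:
    """Posterior-mean trajectory E(y_hat_tj) and the cut-point pmf.

    The fitted mean at each trial is the draw-average of the
    piecewise-linear mean under that draw's (S, c, coefficients) — i.e.
    model averaging over the no-spiral model and every cut-point,
    weighted by their posterior probabilities.  With all posterior mass
    on a single state the result is exactly (piecewise) linear.
    """
    j = list(draws.individual_ids).index(individual)
    T = _n_trials(draws)
    t = np.arange(1, T + 1, dtype=float)
    c_eff = np.where(draws.S[:, j] == 1, draws.c[:, j], T)
    means = (draws.alpha1[:, j, None]
             + draws.beta1[:, j, None] * np.minimum(t, c_eff[:, None])
             + draws.beta2[:, j, None] * np.maximum(t - c_eff[:, None], 0.0))
    spiral = draws.S[:, j] == 1
    n_cuts = T - 2
    pmf = np.zeros(n_cuts)
    if spiral.any():
        counts = np.bincount(draws.c[spiral, j], minlength=n_cuts + 1)[1:]
        pmf = counts / draws.n_draws  # mass conditional on the full posterior
    return TrajectorySummary(
        trials=t, mean=means.mean(axis=0),
        pr_spiral=float(spiral.mean()),
        cut_pmf=pd.Series(pmf, index=np.arange(1, n_cuts + 1), name="pr"),
    )


def _n_trials(draws: PosteriorDraws) -> int:
    return int(draws.n_trials)


def sensitivity_sweep(cohort: CohortData, priors: PriorConfig,
                      c_delta_grid, config: MCMCConfig) -> pd.DataFrame:
    """Pr(pi_E > pi_I | Y) as a function of the delta prior variance.

    Refits the full model at each grid point with the identical seed
    policy (same seed, fresh chain) so the curve varies only through
    c_delta.  A failed fit is recorded as NaN and the sweep continues.
    """
    rows = []
    for c_delta in c_delta_grid:
        pri = priors.replace(c_delta=float(c_delta))
        try:
            draws = run_spiral_mcmc(cohort, pri, config)
            frac = pi_contrast(draws).frac_positive
            err = ""
        except Exception as exc:  # noqa: BLE001 - per-point failure recorded
            frac, err = np.nan, str(exc)
        rows.append({"c_delta": float(c_delta),
                     "pr_pi_E_gt_pi_I": frac, "error": err})
    return pd.DataFrame(rows)


def prior_pi_cdf(c_delta: float, p) -> np.ndarray:
    """Prior CDF of pi = logistic(delta), delta ~ N(0, c_delta)."""
    return ndtr(logit(np.asarray(p, dtype=float)) / np.sqrt(c_delta))


def prior_induced_pi(c_delta: float, interval: tuple[float, float]) -> float:
    """Prior probability that the spiral propensity pi lies in [a, b].

    Closed form Phi(logit(b)/sqrt(c_delta)) - Phi(logit(a)/sqrt(c_delta)).
    Requires 0 < a < b < 1 and c_delta > 0.
    """
    a, b = interval
    if not (0.0 <= a < b <= 1.0):
        raise ValueError("need 0 <= a < b <= 1")
    if c_delta <= 0:
        raise ValueError("c_delta must be positive")
    return float(prior_pi_cdf(c_delta, b) - prior_pi_cdf(c_delta, a))
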