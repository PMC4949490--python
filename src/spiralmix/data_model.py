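"""Domain types and I/O for multi-trial performance cohorts.

The central container is :class:`CohortData`: a complete J x T grid of
performance scores (one score per individual per trial) together with a
binary group label per individual.  Groups arise from an 8-item implicit
theory of ability (ITA) questionnaire: after reverse-scoring the
incremental-type items, a higher scale score indicates a stronger
incremental theory; a median split assigns each respondent to the
``entity`` (below median) or ``incremental`` (above median) group.

Scores are on a percentage-of-budgeted-hours scale whose task norm is 100,
so typical values lie in the 80-140 range.  Trials are indexed 1..T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ENTITY = "entity"
INCREMENTAL = "incremental"
GROUP_LABELS = (ENTITY, INCREMENTAL)

__all__ = [
    "ENTITY",
    "INCREMENTAL",
    "GROUP_LABELS",
    "ItaResponse",
    "ItaClassification",
    "CohortData",
    "score_ita",
    "median_split",
    "read_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class ItaResponse:
    """One respondent's 8-item ITA questionnaire.

    Parameters
    ----------
    item_values
        Eight integers on the 1-6 Likert scale (1 = strongly agree,
        6 = strongly disagree).
    item_polarity
        Eight flags, one per item: ``"entity"`` for entity-type items,
        ``"incremental"`` for incremental-type items.  Exactly four of each.
    """

    item_values: tuple[int, ...]
    item_polarity: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.item_values) != 8 or len(self.item_polarity) != 8:
            raise ValueError("an ITA response has exactly 8 items")
        for i, v in enumerate(self.item_values):
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 6):
                raise ValueError(
                    f"item {i + 1} has value {v!r}; Likert responses must be "
                    "integers in 1..6"
                )
        for i, p in enumerate(self.item_polarity):
            if p not in GROUP_LABELS:
                raise ValueError(f"item {i + 1} has unknown polarity {p!r}")
        n_entity = sum(p == ENTITY for p in self.item_polarity)
        if n_entity != 4:
            raise ValueError(
                f"expected 4 entity-type and 4 incremental-type items, got "
                f"{n_entity} entity-type"
            )


@dataclass(frozen=True)
class ItaClassification:
    """Scale scores and median-split group labels for a cohort.

    ``scores`` are mean item scores (Likert units, in [1, 6]); higher means a
    stronger incremental theory.  ``sums`` are the raw item sums (in [8, 48])
    kept for transparency.  ``labels`` partition the cohort at the median;
    ``n_ties`` records how many individuals sat exactly at the median (they
    are assigned to the entity group by convention).
    """

    scores: tuple[float, ...]
    labels: tuple[str, ...]
    sums: tuple[float, ...] = ()
    median: float = float("nan")
    n_ties: int = 0


def reverse_score(values: np.ndarray | list[int]) -> np.ndarray:
    """Map Likert responses v -> 7 - v (an involution on the 1..6 scale)."""
    return 7 - np.asarray(values)


def score_ita(response: ItaResponse) -> float:
    """Score one ITA response: reverse the incremental items, average all 8.

    Returns the mean item score in [1, 6]; higher indicates a stronger
    incremental theory of ability.  (The raw sum is ``8 * score``.)
    """
    values = np.asarray(response.item_values, dtype=float)
    incremental = np.asarray([p == INCREMENTAL for p in response.item_polarity])
    values[incremental] = reverse_score(values[incremental])
    return float(values.mean())


def median_split(scores: list[float] | np.ndarray) -> ItaClassification:
    """Classify individuals as entity (low) or incremental (high) at the median.

    Individuals strictly below the median are entity theorists, strictly
    above are incremental theorists.  Individuals exactly at the median go to
    the entity (lower) group; the number of such ties is recorded in
    ``n_ties`` so the convention is visible in the output.

    Raises
    ------
    ValueError
        If fewer than two scores are given or all scores are identical
        (the split is undefined).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("median split needs at least 2 individuals")
    if np.ptp(scores) == 0:
        raise ValueError("all ITA scores identical; median split undefined")
    med = float(np.median(scores))
    labels = tuple(INCREMENTAL if s > med else ENTITY for s in scores)
    n_ties = int(np.sum(scores == med))
    return ItaClassification(
        scores=tuple(float(s) for s in scores),
        labels=labels,
        median=med,
        n_ties=n_ties,
    )


@dataclass
class CohortData:
    """A complete J x T grid of performance scores with per-individual groups.

    Attributes
    ----------
    individual_ids
        J labels (any hashable, typically ints or strings).
    groups
        Per-individual group label, ``"entity"`` or ``"incremental"``.
    scores
        Array of shape (J, T); ``scores[j, t-1]`` is individual j's
        performance on trial t.  Trials are 1-based and dense: every
        individual has a score for every t in 1..T.
    """

    individual_ids: list
    groups: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a J x T array")
        J, T = self.scores.shape
        if J < 1:
            raise ValueError("need at least one individual")
        if T < 4:
            raise ValueError(
                "need T >= 4 trials (at least one admissible cut-point with "
                "the last two trials excluded)"
            )
        if len(self.individual_ids) != J or len(self.groups) != J:
            raise ValueError("ids, groups and score rows must align")
        for g in self.groups:
            if g not in GROUP_LABELS:
                raise ValueError(f"unknown group label {g!r}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @property
    def n_individuals(self) -> int:
        return self.scores.shape[0]

    @property
    def n_trials(self) -> int:
        return self.scores.shape[1]

    @property
    def trials(self) -> np.ndarray:
        """1-based trial index vector t = 1..T."""
        return np.arange(1, self.n_trials + 1)

    def group_indicator(self) -> np.ndarray:
        """Per-individual group index: 0 = entity, 1 = incremental.

        This encodes the one-hot design z_j = (1, 0) for entity theorists and
        (0, 1) for incremental theorists as an index into length-2 parameter
        vectors.
        """
        return np.asarray(
            [0 if g == ENTITY else 1 for g in self.groups], dtype=int
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: columns individual, group, trial, score."""
        J, T = self.scores.shape
        return pd.DataFrame(
            {
                "individual": np.repeat(self.individual_ids, T),
                "group": np.repeat(self.groups, T),
                "trial": np.tile(np.arange(1, T + 1), J),
                "score": self.scores.ravel(),
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortData):
            return NotImplemented
        return (
            list(self.individual_ids) == list(other.individual_ids)
            and list(self.groups) == list(other.groups)
            and self.scores.shape == other.scores.shape
            and np.allclose(self.scores, other.scores)
        )


def write_cohort(cohort: CohortData, path) -> None:
    """Write a cohort as long-format CSV (individual, group, trial, score)."""
    cohort.to_frame().to_csv(path, index=False)


def read_cohort(path) -> CohortData:
    """Read a long-format CSV (individual, group, trial, score) into a cohort.

    The trial grid must be dense: every individual needs a score for every
    trial 1..T.  Missing (individual, trial) cells are an error (the model
    assumes complete grids; no imputation is attempted).
    """
    df = pd.read_csv(path)
    required = {"individual", "group", "trial", "score"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing_cols)}")
    bad_groups = set(df["group"].unique()) - set(GROUP_LABELS)
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")

    ids = list(pd.unique(df["individual"]))
    T = int(df["trial"].max())
    expected = set(range(1, T + 1))
    gaps = []
    for ind, sub in df.groupby("individual", sort=False):
        got = set(int(t) for t in sub["trial"])
        gaps.extend((ind, t) for t in sorted(expected - got))
    if gaps:
        raise ValueError(f"missing (individual, trial) cells: {gaps}")

    wide = df.pivot_table(
        index="individual", columns="trial", values="score", sort=False
    ).loc[ids, range(1, T + 1)]
    groups = [str(df.loc[df["individual"] == i, "group"].iloc[0]) for i in ids]
    return CohortData(
        individual_ids=ids, groups=groups, scores=wide.to_numpy()
    )
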