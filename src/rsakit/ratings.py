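"""Likert rating tasks: per-stimulus means, split-half reliability,
between-task correlations, and the 2-D PCA of action ratings.

Each rating task asks participants to score every stimulus once on a 1-7
integer scale (e.g. how much the arm moves when using the object).  Analyses
work on the participant x stimulus table of one task, or on the stimulus x
task matrix of mean profiles across tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .design import StimulusSet
from .triplets import spearman_brown

__all__ = [
    "RatingTable",
    "mean_ratings",
    "group_means_with_ci",
    "rating_reliability",
    "task_correlation_matrix",
    "action_pca",
]

RATING_MIN, RATING_MAX = 1, 7


@dataclass
class RatingTable:
    """One task's ratings as a participant x stimulus table of integers 1-7.

    NaN marks a stimulus a participant did not rate; each participant rates
    each stimulus at most once by construction of the wide table.
    """

    task_name: str
    ratings: pd.DataFrame  # index: participant_id, columns: stimulus_id

    def __post_init__(self) -> None:
        vals = self.ratings.to_numpy(dtype=float)
        defined = vals[~np.isnan(vals)]
        if defined.size and (
            (defined < RATING_MIN).any()
            or (defined > RATING_MAX).any()
            or not np.allclose(defined, np.round(defined))
        ):
            raise ValueError("ratings must be integers in 1..7")

    @property
    def n_participants(self) -> int:
        return len(self.ratings)

    @staticmethod
    def from_long(df: pd.DataFrame, task_name: str | None = None) -> "RatingTable":
        """Build from a long table with participant_id, stimulus_id, rating
        (and optionally a task column to select on)."""
        if task_name is not None and "task" in df.columns:
            df = df[df["task"] == task_name]
        elif task_name is None:
            tasks = df["task"].unique() if "task" in df.columns else ["task"]
            if len(tasks) != 1:
                raise ValueError("long table holds several tasks; pass task_name")
            task_name = str(tasks[0])
        if df.duplicated(["participant_id", "stimulus_id"]).any():
            raise ValueError("a participant rated a stimulus more than once")
        wide = df.pivot(index="participant_id", columns="stimulus_id", values="rating")
        return RatingTable(task_name, wide)


def mean_ratings(table: RatingTable) -> pd.Series:
    """Arithmetic mean rating per stimulus (the task's mean profile)."""
    counts = table.ratings.notna().sum(axis=0)
    if (counts == 0).any():
        empty = list(counts.index[counts == 0])
        raise ValueError(f"stimuli with zero ratings: {empty[:5]}")
    return table.ratings.mean(axis=0)


def group_means_with_ci(
    table: RatingTable, design: StimulusSet, by: str = "object_type"
) -> pd.DataFrame:
    """Mean rating per stimulus group with a 95% normal CI on the mean.

    Groups stimuli by ``object_type`` or ``aspect_ratio`` from the design and
    pools all ratings of the group's stimuli; the CI is mean +/- 1.96 * SEM
    (the normal-distribution CI centered on the mean used for error bars).
    """
    labels = pd.Series(
        design.object_types if by == "object_type" else design.aspect_ratios,
        index=list(design.ids),
    )
    long = (
        table.ratings.rename_axis(index="participant_id", columns="stimulus_id")
        .stack()
        .rename("rating")
        .reset_index()
    )
    long["group"] = long["stimulus_id"].map(labels)
    if long["group"].isna().any():
        raise ValueError("rating table contains stimuli absent from the design")
    out = []
    for g, block in long.groupby("group", sort=False):
        vals = block["rating"].to_numpy()
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        out.append(
            {
                "group": g,
                "mean": vals.mean(),
                "ci_low": vals.mean() - 1.96 * sem,
                "ci_high": vals.mean() + 1.96 * sem,
                "n": len(vals),
            }
        )
    return pd.DataFrame(out).set_index("group")


def rating_reliability(
    table: RatingTable, n_splits: int = 1000, seed: int | None = None
) -> float:
    """Split-half reliability of a task's mean profile, Spearman-Brown corrected.

    Participants are randomly split into halves; the two half-sample mean
    stimulus profiles are Pearson-correlated; the mean over splits is passed
    through the Spearman-Brown formula.
    """
    if table.n_participants < 2:
        raise ValueError("reliability needs at least 2 participants")
    rng = np.random.default_rng(seed)
    vals = table.ratings.to_numpy(dtype=float)
    n = vals.shape[0]
    rs = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        first = np.zeros(n, dtype=bool)
        first[perm[: n // 2]] = True
        m1 = np.nanmean(vals[first], axis=0)
        m2 = np.nanmean(vals[~first], axis=0)
        ok = ~np.isnan(m1) & ~np.isnan(m2)
        if ok.sum() < 3 or np.ptp(m1[ok]) == 0 or np.ptp(m2[ok]) == 0:
            continue
        rs.append(stats.pearsonr(m1[ok], m2[ok])[0])
    if not rs:
        raise ValueError("no usable split (too few common stimuli or constant profiles)")
    return spearman_brown(float(np.mean(rs)))


def task_correlation_matrix(
    mean_profiles: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between task mean profiles.

    ``mean_profiles`` is stimuli x tasks.  Returns (r, p) DataFrames; a task
    with a constant profile has undefined correlations and is flagged with
    NaN entries plus a warning.
    """
    import warnings

    tasks = list(mean_profiles.columns)
    if len(tasks) < 2:
        raise ValueError("need at least 2 tasks")
    r = pd.DataFrame(np.eye(len(tasks)), index=tasks, columns=tasks)
    p = pd.DataFrame(np.zeros((len(tasks), len(tasks))), index=tasks, columns=tasks)
    const = [t for t in tasks if np.ptp(mean_profiles[t].to_numpy()) == 0]
    if const:
        warnings.warn(
            f"constant mean profile(s) {const}: correlations undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    for i, ti in enumerate(tasks):
        for j in range(i + 1, len(tasks)):
            tj = tasks[j]
            if ti in const or tj in const:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(
                    mean_profiles[ti].to_numpy(), mean_profiles[tj].to_numpy()
                )
            r.loc[ti, tj] = r.loc[tj, ti] = rij
            p.loc[ti, tj] = p.loc[tj, ti] = pij
    return r, p


def action_pca(
    mean_profiles: pd.DataFrame,
    n_components: int = 2,
    standardize: bool = True,
) -> tuple[pd.DataFrame, float, np.ndarray]:
    """PCA of the stimulus x task matrix of mean action ratings.

    Task profiles are z-scored by default (the tasks share the 1-7 scale but
    differ in spread).  Returns the stimulus scores on the first
    ``n_components`` components, the cumulative variance fraction they
    explain, and the full per-component variance-fraction vector.
    """
    if mean_profiles.shape[1] < 2 or mean_profiles.shape[0] < 3:
        raise ValueError("need at least 2 tasks and 3 stimuli")
    x = mean_profiles.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        if (sd == 0).any():
            raise ValueError("cannot standardize a constant task profile")
        x = (x - x.mean(axis=0)) / sd
    else:
        x = x - x.mean(axis=0)
    if np.linalg.matrix_rank(x) < min(x.shape):
        import warnings

        warnings.warn("rank-deficient rating matrix", RuntimeWarning, stacklevel=2)
    pca = PCA()
    scores = pca.fit_transform(x)
    k = min(n_components, scores.shape[1])
    frac = pca.explained_variance_ratio_
    score_df = pd.DataFrame(
        scores[:, :k],
        index=mean_profiles.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return score_df, float(frac[:k].sum()), frac
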