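"""Odd-one-out triplet judgments: enumeration, chunking, quality control,
RDM aggregation, and split-half reliability.

In the odd-one-out task a participant sees three stimuli and picks the one
unlike the other two.  The pairwise dissimilarity of stimuli *i* and *j* is
the fraction of trials containing both on which either *i* or *j* was picked
as the odd one: picking a third stimulus is evidence that *i* and *j* belong
together.  With 48 stimuli there are C(48, 3) = 17296 unique triplets, which
the data-collection design partitions into 412 chunks of 42 trials (one of
34) assigned to participants one chunk per session.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rdm import RDM

__all__ = [
    "TripletTrial",
    "TripletDataset",
    "QCReport",
    "enumerate_triplets",
    "chunk_trials",
    "qc_filter",
    "aggregate_rdm",
    "split_half_reliability",
    "spearman_brown",
]

TRIAL_COLUMNS = [
    "participant_id",
    "session_id",
    "stim_a",
    "stim_b",
    "stim_c",
    "choice",
    "rt_ms",
]


@dataclass(frozen=True)
class TripletTrial:
    """One odd-one-out trial: a presented triplet, the choice, and RT.

    ``triplet`` stores the three stimuli in presentation order so that the
    chosen response *position* (needed by the uniform-responding check) is
    recoverable, but all aggregation treats it as unordered.
    """

    participant_id: str
    triplet: tuple[str, str, str]
    choice: str
    rt_ms: float
    session_id: str = "0"

    def __post_init__(self) -> None:
        if len(set(self.triplet)) != 3:
            raise ValueError("triplet members must be distinct")
        if self.choice not in self.triplet:
            raise ValueError("choice must be a member of the triplet")
        if self.rt_ms < 0:
            raise ValueError("rt_ms must be nonnegative")

    @property
    def choice_position(self) -> int:
        return self.triplet.index(self.choice)


class TripletDataset:
    """Trial-level odd-one-out responses over a fixed stimulus universe."""

    def __init__(self, trials: pd.DataFrame | list[TripletTrial], stimulus_ids):
        if isinstance(trials, list):
            trials = pd.DataFrame(
                [
                    {
                        "participant_id": t.participant_id,
                        "session_id": t.session_id,
                        "stim_a": t.triplet[0],
                        "stim_b": t.triplet[1],
                        "stim_c": t.triplet[2],
                        "choice": t.choice,
                        "rt_ms": t.rt_ms,
                    }
                    for t in trials
                ],
                columns=TRIAL_COLUMNS,
            )
        missing = set(TRIAL_COLUMNS) - set(trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}")
        self.trials = trials.reset_index(drop=True)
        self.stimulus_ids = tuple(str(i) for i in stimulus_ids)
        universe = set(self.stimulus_ids)
        used = (
            set(self.trials["stim_a"])
            | set(self.trials["stim_b"])
            | set(self.trials["stim_c"])
        )
        if not used <= universe:
            raise ValueError(
                f"trials reference stimuli outside the universe: {sorted(used - universe)[:5]}"
            )
        choice_ok = (
            (self.trials["choice"] == self.trials["stim_a"])
            | (self.trials["choice"] == self.trials["stim_b"])
            | (self.trials["choice"] == self.trials["stim_c"])
        )
        if not choice_ok.all():
            raise ValueError("every choice must be a member of its triplet")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def enumerate_triplets(n_stimuli: int) -> list[tuple[int, int, int]]:
    """All C(n, 3) unordered triplets of stimulus indices, lexicographic order."""
    if n_stimuli < 3:
        raise ValueError("need at least 3 stimuli to form a triplet")
    return list(itertools.combinations(range(n_stimuli), 3))


def chunk_trials(
    triplets: list, chunk_size: int, seed: int | None = None
) -> list[list]:
    """Randomly permute triplets and partition into consecutive chunks.

    Produces ``floor(len/chunk_size)`` full chunks plus one remainder chunk
    when the division is not exact; the union of chunks is the input and the
    chunks are disjoint.  With 17296 triplets and chunk size 42 this yields
    412 chunks, the last of size 34.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if not triplets:
        raise ValueError("no triplets to chunk")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(triplets))
    shuffled = [triplets[i] for i in order]
    return [
        shuffled[i : i + chunk_size] for i in range(0, len(shuffled), chunk_size)
    ]


@dataclass
class QCReport:
    """Per-session exclusion bookkeeping from :func:`qc_filter`."""

    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["participant_id", "session_id", "reason", "n_trials"]
        )
    )

    @property
    def n_excluded_sessions(self) -> int:
        return len(self.excluded)


def qc_filter(
    dataset: TripletDataset,
    rt_low_ms: float = 200.0,
    rt_high_ms: float = 10000.0,
) -> tuple[TripletDataset, QCReport]:
    """Exclude sessions that responded uniformly or with implausible RTs.

    A (participant, session) block is excluded iff all its choices are the
    same stimulus, or all its choices fall on the same response position, or
    its median reaction time is below ``rt_low_ms`` or above ``rt_high_ms``.
    Uniform responding is checked on both the chosen stimulus and the chosen
    position; either alone triggers exclusion.
    """
    rows = []
    keep_masks = []
    for (pid, sid), block in dataset.trials.groupby(
        ["participant_id", "session_id"], sort=False
    ):
        reason = None
        med = float(block["rt_ms"].median())
        positions = (
            (block["choice"] == block["stim_a"]).astype(int) * 0
            + (block["choice"] == block["stim_b"]).astype(int) * 1
            + (block["choice"] == block["stim_c"]).astype(int) * 2
        )
        if med < rt_low_ms:
            reason = "rt_low"
        elif med > rt_high_ms:
            reason = "rt_high"
        elif block["choice"].nunique() == 1 or positions.nunique() == 1:
            reason = "uniform"
        if reason is not None:
            rows.append(
                {
                    "participant_id": pid,
                    "session_id": sid,
                    "reason": reason,
                    "n_trials": len(block),
                }
            )
        else:
            keep_masks.append(block.index)
    if keep_masks:
        kept_idx = np.concatenate([np.asarray(ix) for ix in keep_masks])
        kept = dataset.trials.loc[np.sort(kept_idx)]
    else:
        kept = dataset.trials.iloc[0:0]
    report = QCReport(
        pd.DataFrame(rows, columns=["participant_id", "session_id", "reason", "n_trials"])
    )
    return TripletDataset(kept, dataset.stimulus_ids), report


def _counts(
    trials: pd.DataFrame, index: dict[str, int], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Co-occurrence and odd-one-out counts for every stimulus pair."""
    a = trials["stim_a"].map(index).to_numpy()
    b = trials["stim_b"].map(index).to_numpy()
    c = trials["stim_c"].map(index).to_numpy()
    ch = trials["choice"].map(index).to_numpy()
    cooc = np.zeros((n, n))
    odd = np.zeros((n, n))
    for x, y in ((a, b), (a, c), (b, c)):
        np.add.at(cooc, (x, y), 1)
        np.add.at(cooc, (y, x), 1)
        hit = ((ch == x) | (ch == y)).astype(float)
        np.add.at(odd, (x, y), hit)
        np.add.at(odd, (y, x), hit)
    return cooc, odd


def aggregate_rdm(dataset: TripletDataset) -> tuple[RDM, np.ndarray]:
    """Aggregate triplet choices into a behavioral RDM.

    ``d(i, j)`` is the number of trials containing both *i* and *j* on which
    the choice was *i* or *j*, divided by the number of trials containing
    both.  Pairs that never co-occur are NaN (flagged missing, never silently
    zero).  Returns the RDM and the co-occurrence count matrix.
    """
    if len(dataset) == 0:
        raise ValueError("cannot aggregate an empty dataset")
    ids = dataset.stimulus_ids
    index = {s: k for k, s in enumerate(ids)}
    cooc, odd = _counts(dataset.trials, index, len(ids))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = odd / cooc
    d[cooc == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return (
        RDM(d, ids, source="behavioral", distance_name="odd-one-out rate"),
        cooc,
    )


def spearman_brown(r: float) -> float:
    """Spearman-Brown prophecy for a split-half correlation: 2r / (1 + r)."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if r == -1.0:
        raise ValueError("Spearman-Brown is undefined at r = -1")
    return 2.0 * r / (1.0 + r)


def split_half_reliability(
    dataset: TripletDataset,
    n_splits: int = 1000,
    seed: int | None = None,
    split_unit: str = "trial",
    method: str = "pearson",
    min_common_pairs: int = 3,
) -> float:
    """Split-half reliability of the aggregated RDM, Spearman-Brown corrected.

    For each of ``n_splits`` random splits the trials (or whole sessions) are
    partitioned into halves, an RDM is aggregated per half, and the two
    lower triangles are correlated over the pairs defined in both halves.
    The mean correlation across splits is passed through the Spearman-Brown
    formula, estimating the reliability of the full-sample group average.

    Splits with fewer than ``min_common_pairs`` jointly defined pairs are
    skipped; if every split is skipped an error is raised.
    """
    from scipy import stats

    if split_unit not in ("trial", "session"):
        raise ValueError("split_unit must be 'trial' or 'session'")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    rng = np.random.default_rng(seed)
    trials = dataset.trials
    ids = dataset.stimulus_ids
    index = {s: k for k, s in enumerate(ids)}
    n = len(ids)

    if split_unit == "session":
        keys = trials[["participant_id", "session_id"]].apply(tuple, axis=1)
        units = keys.unique()
        unit_of_trial = keys.to_numpy()
    else:
        units = np.arange(len(trials))

    r_sum, r_count = 0.0, 0
    tril = np.tril_indices(n, k=-1)
    for _ in range(n_splits):
        perm = rng.permutation(len(units))
        half_units = set(np.asarray(units, dtype=object)[perm[: len(units) // 2]])
        if split_unit == "session":
            in_first = np.array([u in half_units for u in unit_of_trial])
        else:
            in_first = np.zeros(len(trials), dtype=bool)
            in_first[perm[: len(units) // 2]] = True
        halves = []
        for mask in (in_first, ~in_first):
            cooc, odd = _counts(trials[mask], index, n)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = odd / cooc
            d[cooc == 0] = np.nan
            halves.append(d[tril])
        v1, v2 = halves
        ok = ~np.isnan(v1) & ~np.isnan(v2)
        if ok.sum() < min_common_pairs:
            continue
        if np.ptp(v1[ok]) == 0 or np.ptp(v2[ok]) == 0:
            continue
        if method == "pearson":
            r = stats.pearsonr(v1[ok], v2[ok])[0]
        else:
            r = stats.spearmanr(v1[ok], v2[ok])[0]
        r_sum += r
        r_count += 1
    if r_count == 0:
        raise ValueError("no split produced enough jointly defined pairs")
    return spearman_brown(r_sum / r_count)
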