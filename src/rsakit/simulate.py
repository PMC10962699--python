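"""Synthetic generators for every input the pipeline consumes.

The generators emulate the statistical structure the analyses assume, so the
whole pipeline is testable without any data download:

* triplet choices follow a Luce-style softmax over "oddness" scores derived
  from a latent ground-truth RDM, with a decision temperature and a lapse
  rate;
* Likert ratings are a true per-stimulus score plus participant and trial
  noise, rounded and clipped into 1..7;
* subject voxel patterns are drawn so the stimulus-by-stimulus correlation
  structure follows ``1 - truth`` (nearest-PSD projected), plus independent
  measurement noise;
* statistical map pairs are smooth Gaussian blobs with a controllable
  center displacement, hence controllable true overlap.

The defaults define the study-like conditions: a ground truth dominated by
the object-type model with a weaker shape contribution, low decision noise,
and sample sizes comparable to one scanning cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .design import (
    StimulusSet,
    build_default_design,
    make_shape_model_rdm,
    make_type_model_rdm,
)
from .ratings import RatingTable
from .rdm import RDM, ResponseMatrix
from .roi import ROIMask, StatMap
from .triplets import TripletDataset

__all__ = [
    "GeneratorConfig",
    "make_truth_rdm",
    "simulate_triplet_responses",
    "simulate_ratings",
    "simulate_subject_patterns",
    "simulate_stat_maps",
]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study.

    ``type_weight``/``shape_weight`` mix the object-type and shape model RDMs
    into the ground truth (type-dominant by default, as in the behavioral
    data the pipeline targets).  ``decision_temperature`` scales softmax
    choice noise (0 = deterministic argmax); ``lapse_rate`` is the chance of
    a uniformly random choice.  Pattern generation uses ``n_voxels`` channels
    and adds N(0, pattern_noise_sd) measurement noise.  Map generation draws
    two Gaussian blobs ``blob_displacement`` voxels apart on ``map_grid``.
    """

    design: StimulusSet = field(default_factory=build_default_design)
    type_weight: float = 1.0
    shape_weight: float = 0.3
    decision_temperature: float = 0.05
    lapse_rate: float = 0.02
    n_participants: int = 12
    n_trials_per_participant: int = 42
    n_voxels: int = 200
    pattern_noise_sd: float = 0.6
    map_grid: tuple[int, int, int] = (24, 24, 24)
    blob_displacement: float = 4.0
    blob_sigma: float = 3.0
    blob_peak: float = 6.0
    map_noise_sd: float = 0.0
    rt_median_ms: float = 800.0
    rt_sigma: float = 0.4
    rating_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type_weight < 0 or self.shape_weight < 0:
            raise ValueError("mixture weights must be nonnegative")
        if self.type_weight == 0 and self.shape_weight == 0:
            raise ValueError("at least one mixture weight must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")
        for name in ("n_participants", "n_trials_per_participant", "n_voxels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_truth_rdm(config: GeneratorConfig) -> RDM:
    """Ground-truth RDM: weighted sum of type and shape models, scaled to [0, 1]."""
    type_rdm = make_type_model_rdm(config.design)
    shape_rdm = make_shape_model_rdm(config.design)
    values = config.type_weight * type_rdm.values + config.shape_weight * shape_rdm.values
    values = values / values.max()
    return RDM(values, config.design.ids, source="model", distance_name="truth")


def simulate_triplet_responses(
    truth: RDM,
    config: GeneratorConfig,
    full_enumeration: bool = False,
    rng: np.random.Generator | None = None,
) -> TripletDataset:
    """Sample odd-one-out judgments from a latent dissimilarity structure.

    Each trial presents a triplet {i, j, k}; the oddness score of a member is
    the sum of its truth dissimilarities to the other two, and the choice is
    a softmax over oddness at ``decision_temperature`` (argmax as the
    temperature approaches 0).  With probability ``lapse_rate`` the choice is
    uniform instead.  Reaction times are log-normal with median
    ``rt_median_ms``, so quality-control paths are exercisable.

    With ``full_enumeration`` every one of the C(n, 3) triplets is presented
    exactly once, split across participants; otherwise each participant
    answers ``n_trials_per_participant`` random triplets.
    """
    if truth.ids != config.design.ids:
        raise ValueError("truth RDM must be defined on the configured design")
    rng = config.rng() if rng is None else rng
    n = truth.n
    ids = truth.ids
    d = truth.values

    if full_enumeration:
        trip = np.array(list(combinations(range(n), 3)))
        trip = trip[rng.permutation(len(trip))]
        parts = np.arange(len(trip)) % config.n_participants
    else:
        total = config.n_participants * config.n_trials_per_participant
        trip = np.empty((total, 3), dtype=int)
        for t in range(total):
            trip[t] = rng.choice(n, size=3, replace=False)
        parts = np.repeat(np.arange(config.n_participants), config.n_trials_per_participant)

    i, j, k = trip[:, 0], trip[:, 1], trip[:, 2]
    odd = np.column_stack(
        [d[i, j] + d[i, k], d[j, i] + d[j, k], d[k, i] + d[k, j]]
    )
    temp = config.decision_temperature
    if temp <= 0:
        # deterministic argmax with index tie-break
        choice_pos = np.argmax(odd, axis=1)
    else:
        z = odd / temp
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(len(trip))
        choice_pos = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    lapse = rng.random(len(trip)) < config.lapse_rate
    choice_pos[lapse] = rng.integers(0, 3, size=int(lapse.sum()))

    # present the triplet in random order so response positions vary
    order = np.argsort(rng.random((len(trip), 3)), axis=1)
    presented = np.take_along_axis(trip, order, axis=1)
    chosen = trip[np.arange(len(trip)), choice_pos]

    mu = np.log(config.rt_median_ms)
    rts = rng.lognormal(mean=mu, sigma=config.rt_sigma, size=len(trip))

    id_arr = np.asarray(ids)
    trials = pd.DataFrame(
        {
            "participant_id": [f"p{p:03d}" for p in parts],
            "session_id": "0",
            "stim_a": id_arr[presented[:, 0]],
            "stim_b": id_arr[presented[:, 1]],
            "stim_c": id_arr[presented[:, 2]],
            "choice": id_arr[chosen],
            "rt_ms": rts,
        }
    )
    return TripletDataset(trials, ids)


def simulate_ratings(
    true_profile: pd.Series,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> RatingTable:
    """Likert ratings: truth + participant offset + trial noise, into 1..7.

    Participant offsets are N(0, rating_noise_sd / 2); trial noise is
    N(0, rating_noise_sd); a zero ``rating_noise_sd`` reproduces the rounded
    truth exactly.
    """
    if not np.all(np.isfinite(true_profile.to_numpy(dtype=float))):
        raise ValueError("true profile must be finite")
    rng = config.rng() if rng is None else rng
    truth = true_profile.to_numpy(dtype=float)
    n_p = config.n_participants
    sd = config.rating_noise_sd
    offsets = rng.normal(0.0, sd / 2.0, size=n_p) if sd > 0 else np.zeros(n_p)
    noise = (
        rng.normal(0.0, sd, size=(n_p, len(truth)))
        if sd > 0
        else np.zeros((n_p, len(truth)))
    )
    raw = truth[None, :] + offsets[:, None] + noise
    clipped = np.clip(np.round(raw), 1, 7)
    table = pd.DataFrame(
        clipped,
        index=[f"p{i:03d}" for i in range(n_p)],
        columns=list(true_profile.index),
    )
    return RatingTable("synthetic", table)


def _nearest_psd(c: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def simulate_subject_patterns(
    truth: RDM,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, ResponseMatrix]:
    """Voxel patterns whose stimulus correlation structure follows the truth.

    Each voxel's response profile across stimuli is drawn from a zero-mean
    multivariate normal with covariance ``1 - truth`` (projected to the
    nearest PSD matrix), plus independent N(0, pattern_noise_sd) noise per
    entry.  As ``n_voxels`` grows and the noise shrinks, the empirical 1-r
    RDM converges in rank order to the truth.
    """
    rng = config.rng() if rng is None else rng
    cov = _nearest_psd(1.0 - truth.values)
    n = truth.n
    # factor once; reused across participants
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    out = {}
    for p in range(config.n_participants):
        z = rng.standard_normal((n, config.n_voxels))
        signal = root @ z
        noise = rng.normal(0.0, config.pattern_noise_sd, size=(n, config.n_voxels))
        out[f"p{p:03d}"] = ResponseMatrix(
            signal + noise, truth.ids, participant_id=f"p{p:03d}"
        )
    return out


def simulate_stat_maps(
    config: GeneratorConfig,
    p_threshold: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[StatMap, StatMap, ROIMask, float]:
    """A pair of blob maps with controllable true overlap, plus a mask.

    Two Gaussian-profile statistics (peak ``blob_peak``, width ``blob_sigma``)
    are centered ``blob_displacement`` voxels apart along the first axis,
    with optional N(0, map_noise_sd) background noise.  p-values are the
    upper-tail normal probabilities of the statistics.  ``true_overlap`` is
    the Jaccard index of the noise-free suprathreshold (p < p_threshold)
    voxel sets - the value the thresholded-overlap pipeline should recover
    exactly in the noise-free case.
    """
    from scipy import stats as sps

    rng = config.rng() if rng is None else rng
    shape = tuple(config.map_grid)
    center = np.array(shape, dtype=float) / 2.0
    half = config.blob_displacement / 2.0
    c_a = center + np.array([-half, 0.0, 0.0])
    c_b = center + np.array([+half, 0.0, 0.0])
    sigma = config.blob_sigma
    # the suprathreshold radius at the chosen p threshold
    z_thr = sps.norm.isf(p_threshold)
    if config.blob_peak <= z_thr:
        raise ValueError("blob peak too low to clear the p threshold")
    r_thr = sigma * np.sqrt(2.0 * np.log(config.blob_peak / z_thr))
    for c in (c_a, c_b):
        if np.any(c - r_thr < 0) or np.any(c + r_thr > np.array(shape) - 1):
            raise ValueError("blob exits the grid at the requested displacement")

    grid = np.indices(shape, dtype=float)

    def blob(c: np.ndarray) -> np.ndarray:
        d2 = sum((grid[ax] - c[ax]) ** 2 for ax in range(3))
        return config.blob_peak * np.exp(-d2 / (2.0 * sigma**2))

    clean_a, clean_b = blob(c_a), blob(c_b)
    sup_a = sps.norm.sf(clean_a) < p_threshold
    sup_b = sps.norm.sf(clean_b) < p_threshold
    union = (sup_a | sup_b).sum()
    true_overlap = float((sup_a & sup_b).sum() / union) if union else 0.0

    def finish(clean: np.ndarray) -> StatMap:
        stat = clean + (
            rng.normal(0.0, config.map_noise_sd, size=shape)
            if config.map_noise_sd > 0
            else 0.0
        )
        return StatMap(stat, sps.norm.sf(stat))

    mask = ROIMask(np.ones(shape, dtype=bool), name="whole-grid")
    return finish(clean_a), finish(clean_b), mask, true_overlap
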