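"""Region-of-interest definition and univariate ROI statistics.

ROIs are carved from per-participant statistical contrast maps with an
adaptive threshold rule: starting from the most stringent of a descending
p-threshold ladder, suprathreshold voxels inside an anatomical mask are
clustered (face + edge connectivity) and clusters below a minimum size are
dropped; the first threshold at which voxels survive defines the ROI, and if
none does, no ROI is created for that participant.  Univariate analyses then
average GLM betas over ROI voxels and compare conditions with paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .design import StimulusSet
from .rdm import ResponseMatrix

__all__ = [
    "StatMap",
    "ROIMask",
    "BetaSet",
    "cluster_components",
    "define_roi",
    "top_n_voxels",
    "roi_mean_responses",
    "group_condition_test",
    "rating_response_correlation",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.001, 0.005, 0.01, 0.05)

#: face + edge (18-neighbor) connectivity in 3-D; corners excluded
_STRUCTURE = ndimage.generate_binary_structure(3, 2)


@dataclass
class StatMap:
    """A 3-D statistical contrast map: per-voxel statistic and p-value."""

    stat: np.ndarray
    p: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stat = np.asarray(self.stat, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.stat.shape != self.p.shape:
            raise ValueError("stat and p grids must be congruent")
        if self.stat.ndim != 3:
            raise ValueError("StatMap must be 3-D")
        if np.nanmin(self.p) < 0 or np.nanmax(self.p) > 1:
            raise ValueError("p-values must lie in [0, 1]")
        if self.affine is None:
            self.affine = np.eye(4)

    def to_nifti(self):
        import nibabel as nib

        return (
            nib.Nifti1Image(self.stat.astype(np.float32), self.affine),
            nib.Nifti1Image(self.p.astype(np.float32), self.affine),
        )

    @staticmethod
    def from_nifti(stat_img, p_img) -> "StatMap":
        import nibabel as nib

        if isinstance(stat_img, str):
            stat_img = nib.load(stat_img)
        if isinstance(p_img, str):
            p_img = nib.load(p_img)
        return StatMap(
            np.asarray(stat_img.dataobj, dtype=float),
            np.asarray(p_img.dataobj, dtype=float),
            affine=np.asarray(stat_img.affine),
        )


@dataclass
class ROIMask:
    """A boolean voxel set on a 3-D grid, with the threshold that defined it."""

    mask: np.ndarray
    name: str = ""
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def indices(self) -> np.ndarray:
        """Linear (C-order) voxel indices of the mask, sorted."""
        return np.flatnonzero(self.mask.ravel())


def cluster_components(
    binary_map: np.ndarray, connectivity: str = "face_edge"
) -> tuple[np.ndarray, np.ndarray]:
    """Label connected components of a binary 3-D map.

    ``face_edge`` (default) uses 18-neighbor connectivity: voxels sharing a
    face or an edge are connected, corner-only contact is not.  ``face``
    restricts to 6 neighbors.  Returns (labels, sizes) with sizes[k] the
    voxel count of cluster k+1.
    """
    binary_map = np.asarray(binary_map).astype(bool)
    if binary_map.ndim != 3:
        raise ValueError("binary map must be 3-D")
    if connectivity == "face_edge":
        structure = _STRUCTURE
    elif connectivity == "face":
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 'face_edge' or 'face'")
    labels, n = ndimage.label(binary_map, structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, sizes


def define_roi(
    stat_map: StatMap,
    mask: ROIMask,
    thresholds=DEFAULT_THRESHOLDS,
    min_cluster: int = 40,
    name: str = "",
) -> ROIMask | None:
    """Adaptive-threshold ROI definition within an anatomical mask.

    At each p-threshold in order (most stringent first), voxels with
    ``p < threshold`` inside the mask are clustered under face+edge
    connectivity and clusters smaller than ``min_cluster`` are discarded.
    The first threshold at which any cluster survives defines the ROI.  If
    no threshold succeeds, returns None (no ROI for this participant).
    """
    if stat_map.stat.shape != mask.mask.shape:
        raise ValueError("stat map and mask are on different grids")
    for thr in thresholds:
        supra = (stat_map.p < thr) & mask.mask
        if not supra.any():
            continue
        labels, sizes = cluster_components(supra)
        keep = np.flatnonzero(sizes >= min_cluster) + 1
        if keep.size == 0:
            continue
        roi = np.isin(labels, keep)
        return ROIMask(roi, name=name, threshold=float(thr))
    return None


def top_n_voxels(stat_map: StatMap, mask: ROIMask, n: int) -> ROIMask:
    """The n most selective voxels within a mask, without clustering.

    Selectivity is the contrast statistic; ties at the cutoff are broken by
    linear voxel index, so the result is deterministic across runs.
    """
    if stat_map.stat.shape != mask.mask.shape:
        raise ValueError("stat map and mask are on different grids")
    candidates = np.flatnonzero(mask.mask.ravel())
    if n > candidates.size:
        raise ValueError(f"n = {n} exceeds the {candidates.size}-voxel mask")
    vals = stat_map.stat.ravel()[candidates]
    # stable sort on (-stat, linear index): mergesort keeps index order in ties
    order = np.argsort(-vals, kind="mergesort")
    chosen = candidates[order[:n]]
    out = np.zeros(mask.mask.size, dtype=bool)
    out[chosen] = True
    return ROIMask(out.reshape(mask.mask.shape), name=f"top{n}")


class BetaSet:
    """Per-participant stimulus x voxel betas restricted to one ROI,
    with condition labels shared across participants."""

    def __init__(
        self,
        patterns: dict[str, ResponseMatrix],
        design: StimulusSet,
    ):
        if not patterns:
            raise ValueError("empty BetaSet")
        ref_ids = None
        for pid, pm in patterns.items():
            if ref_ids is None:
                ref_ids = pm.stimulus_ids
            elif pm.stimulus_ids != ref_ids:
                raise ValueError(
                    f"participant {pid} has mismatched stimulus labels"
                )
        design_ids = set(design.ids)
        if not set(ref_ids) <= design_ids:
            raise ValueError("BetaSet stimuli missing from the design")
        self.patterns = dict(patterns)
        self.design = design
        self.stimulus_ids = ref_ids

    @property
    def participant_ids(self) -> list[str]:
        return list(self.patterns)

    def labels(self, grouping: str) -> np.ndarray:
        lookup = {
            s.stimulus_id: {
                "exemplar": s.stimulus_id,
                "object_type": s.object_type,
                "shape_type": s.aspect_ratio,
            }[grouping]
            for s in self.design
        }
        return np.array([lookup[s] for s in self.stimulus_ids])


def roi_mean_responses(betas: BetaSet, grouping: str = "exemplar") -> pd.DataFrame:
    """Mean ROI response per participant and condition group.

    Averages over voxels, then (for groupings coarser than exemplar) over the
    exemplars of each group.  Returns participants x groups.
    """
    if grouping not in ("exemplar", "object_type", "shape_type"):
        raise ValueError("grouping must be exemplar, object_type or shape_type")
    labels = betas.labels(grouping)
    groups = list(dict.fromkeys(labels))  # stable order of first appearance
    rows = {}
    for pid, pm in betas.patterns.items():
        voxel_mean = pm.values.mean(axis=1)
        rows[pid] = [voxel_mean[labels == g].mean() for g in groups]
    return pd.DataFrame.from_dict(rows, orient="index", columns=groups)


def group_condition_test(
    means: pd.DataFrame, condition_a: str, condition_b: str
) -> tuple[float, int, float]:
    """Paired two-sided t-test of condition A vs B across participants.

    Returns (t, df, p).  A zero-variance difference vector is flagged.
    """
    for c in (condition_a, condition_b):
        if c not in means.columns:
            raise ValueError(f"condition {c!r} not present")
    a = means[condition_a].to_numpy(dtype=float)
    b = means[condition_b].to_numpy(dtype=float)
    if len(a) < 2:
        raise ValueError("paired test needs at least 2 participants")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0) and not np.allclose(diff, 0.0):
        raise ValueError("zero-variance nonzero differences: t undefined")
    if np.allclose(diff, 0.0):
        return 0.0, len(a) - 1, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), len(a) - 1, float(p)


def rating_response_correlation(
    stimulus_values: pd.Series, betas: BetaSet
) -> tuple[pd.Series, tuple[float, int, float]]:
    """Correlate a per-stimulus rating profile with individual ROI responses.

    For each participant, Pearson-correlates the rating values with that
    participant's per-exemplar ROI mean responses over the overlapping
    stimuli; then tests the coefficients against zero with a one-sample
    two-sided t-test.  Returns (per-participant r, (t, df, p)).
    """
    exemplar_means = roi_mean_responses(betas, grouping="exemplar")
    common = [s for s in exemplar_means.columns if s in stimulus_values.index]
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping stimuli")
    ratings = stimulus_values.loc[common].to_numpy(dtype=float)
    rs = {}
    for pid in exemplar_means.index:
        resp = exemplar_means.loc[pid, common].to_numpy(dtype=float)
        rs[pid] = stats.pearsonr(ratings, resp)[0]
    r_series = pd.Series(rs, name="r")
    vals = r_series.to_numpy()
    if np.allclose(vals.std(ddof=1) if len(vals) > 1 else 0.0, 0.0):
        # all coefficients identical (e.g. responses exactly equal ratings)
        t = np.inf if vals.mean() != 0 else 0.0
        p = 0.0 if vals.mean() != 0 else 1.0
    else:
        t, p = stats.ttest_1samp(vals, 0.0)
    return r_series, (float(t), len(vals) - 1, float(p))
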