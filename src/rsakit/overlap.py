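"""Spatial overlap between two selectivity maps: Jaccard index, unique
fractions, and top-N most-selective-voxel overlap curves.

Given food- and tool-selective statistical maps (or any pair of contrast
maps), overlap is quantified as the Jaccard index |A n B| / |A u B| of their
suprathreshold voxel sets, together with the fractions of the union unique to
each map; the three fractions sum to one.  A complementary view thresholds
nothing and instead tracks the Jaccard index of the N most selective voxels
of each map as N grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .roi import ROIMask, StatMap, cluster_components, top_n_voxels

__all__ = [
    "OverlapResult",
    "jaccard_overlap",
    "thresholded_overlap",
    "topn_overlap_curve",
    "group_overlap_tests",
    "DEFAULT_TOPN_SIZES",
]

DEFAULT_TOPN_SIZES = tuple(range(50, 501, 50))


@dataclass(frozen=True)
class OverlapResult:
    """Jaccard overlap and the unique fractions of two voxel sets."""

    jaccard: float
    unique_a: float
    unique_b: float
    n_union: int

    def __post_init__(self) -> None:
        total = self.jaccard + self.unique_a + self.unique_b
        if self.n_union > 0 and not np.isclose(total, 1.0):
            raise ValueError("fractions must sum to 1 over a nonempty union")


def _as_bool(m) -> np.ndarray:
    if isinstance(m, ROIMask):
        return m.mask
    return np.asarray(m).astype(bool)


def jaccard_overlap(map_a, map_b) -> OverlapResult:
    """Jaccard index and unique fractions of two binary voxel sets.

    ``jaccard = |A n B| / |A u B|``; ``unique_a = |A \\ B| / |A u B|`` and
    symmetrically for B.  Raises on an empty union (overlap undefined).
    """
    a, b = _as_bool(map_a), _as_bool(map_b)
    if a.shape != b.shape:
        raise ValueError("maps are on different grids")
    union = int((a | b).sum())
    if union == 0:
        raise ValueError("empty union: overlap undefined")
    inter = int((a & b).sum())
    only_a = int((a & ~b).sum())
    only_b = int((b & ~a).sum())
    return OverlapResult(inter / union, only_a / union, only_b / union, union)


def _threshold_and_cluster(
    stat_map: StatMap, mask: np.ndarray, p_threshold: float, min_cluster: int
) -> np.ndarray:
    supra = (stat_map.p < p_threshold) & mask
    if not supra.any() or min_cluster <= 1:
        return supra
    labels, sizes = cluster_components(supra)
    keep = np.flatnonzero(sizes >= min_cluster) + 1
    return np.isin(labels, keep)


def thresholded_overlap(
    map_a: StatMap,
    map_b: StatMap,
    mask,
    p_threshold: float = 0.05,
    min_cluster: int = 40,
) -> OverlapResult | None:
    """Overlap of two thresholded, cluster-filtered selectivity maps.

    Each map is thresholded at ``p < p_threshold`` within the anatomical
    mask, clusters smaller than ``min_cluster`` voxels (face+edge
    connectivity) are removed, and the Jaccard overlap of the surviving sets
    is computed.  If either map has no surviving voxels the overlap is
    undefined for this participant and None is returned (never zero), so
    such participants can be excluded from group summaries.
    """
    mask = _as_bool(mask)
    if map_a.stat.shape != map_b.stat.shape or map_a.stat.shape != mask.shape:
        raise ValueError("maps and mask are on different grids")
    set_a = _threshold_and_cluster(map_a, mask, p_threshold, min_cluster)
    set_b = _threshold_and_cluster(map_b, mask, p_threshold, min_cluster)
    if not set_a.any() or not set_b.any():
        return None
    return jaccard_overlap(set_a, set_b)


def topn_overlap_curve(
    map_a: StatMap,
    map_b: StatMap,
    mask,
    sizes=DEFAULT_TOPN_SIZES,
) -> pd.DataFrame:
    """Jaccard overlap of the top-N most selective voxels of each map.

    For each N in ``sizes`` the N highest-statistic voxels of each map inside
    the mask are selected (no clustering) and their Jaccard index computed.
    Sizes exceeding the mask are skipped.  Returns a DataFrame with columns
    ``n`` and ``jaccard``.
    """
    mask_arr = _as_bool(mask)
    roi_mask = mask if isinstance(mask, ROIMask) else ROIMask(mask_arr)
    available = int(mask_arr.sum())
    rows = []
    for n in sizes:
        if n > available:
            continue
        a = top_n_voxels(map_a, roi_mask, n).mask
        b = top_n_voxels(map_b, roi_mask, n).mask
        rows.append({"n": int(n), "jaccard": jaccard_overlap(a, b).jaccard})
    return pd.DataFrame(rows, columns=["n", "jaccard"])


def group_overlap_tests(results: list[OverlapResult | None]) -> dict:
    """Group summary of per-participant overlap fractions.

    Undefined participants (None) are dropped, mirroring reduced group sizes
    when some participants show no suprathreshold activation.  Returns the
    mean fractions plus paired two-sided t-tests of the overlap fraction
    against each unique fraction.
    """
    defined = [r for r in results if r is not None]
    if len(defined) < 2:
        raise ValueError("need at least 2 defined participants")
    jac = np.array([r.jaccard for r in defined])
    ua = np.array([r.unique_a for r in defined])
    ub = np.array([r.unique_b for r in defined])
    t_a, p_a = stats.ttest_rel(jac, ua)
    t_b, p_b = stats.ttest_rel(jac, ub)
    return {
        "n": len(defined),
        "n_undefined": len(results) - len(defined),
        "mean_jaccard": float(jac.mean()),
        "mean_unique_a": float(ua.mean()),
        "mean_unique_b": float(ub.mean()),
        "jaccard_vs_unique_a": (float(t_a), len(defined) - 1, float(p_a)),
        "jaccard_vs_unique_b": (float(t_b), len(defined) - 1, float(p_b)),
    }
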