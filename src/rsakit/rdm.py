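"""Representational dissimilarity matrices: construction, comparison, averaging,
noise ceilings, and multidimensional scaling.

An RDM is a symmetric stimulus-by-stimulus matrix of pairwise dissimilarities
with a zero diagonal.  Entries may be NaN where a dissimilarity is undefined
(e.g. a stimulus pair that never co-occurred in a triplet split); every
operation here is missing-aware and correlates only over jointly defined pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.manifold import MDS

__all__ = [
    "RDM",
    "ResponseMatrix",
    "correlation_distance_rdm",
    "lower_triangle_vector",
    "compare_rdms",
    "noise_ceiling",
    "group_average_rdm",
    "mds_embed",
]


@dataclass
class RDM:
    """Symmetric pairwise dissimilarity matrix with provenance metadata.

    Parameters
    ----------
    values : (n, n) array
        Dissimilarities.  NaN marks an undefined (missing) pair.
    ids : sequence of str
        Stimulus identifiers, one per row/column.
    source : str
        Provenance tag: ``"behavioral"``, ``"neural"``, ``"model"`` or
        ``"feature"``.
    distance_name : str
        Human-readable name of the dissimilarity (e.g. ``"1-r"``).
    """

    values: np.ndarray
    ids: tuple[str, ...]
    source: str = "model"
    distance_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = tuple(str(i) for i in self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=False):
            raise ValueError("RDM diagonal must be zero")
        defined = ~np.isnan(self.values)
        if not np.array_equal(defined, defined.T) or not np.allclose(
            self.values[defined & defined.T],
            self.values.T[defined & defined.T],
        ):
            raise ValueError("RDM must be symmetric (NaN pattern included)")
        if np.any(np.isinf(self.values)):
            raise ValueError("RDM entries must be finite or NaN")

    @property
    def n(self) -> int:
        return len(self.ids)

    def lower_triangle(self) -> np.ndarray:
        """Strictly-below-diagonal entries in row-major order."""
        return lower_triangle_vector(self.values)

    def copy(self) -> "RDM":
        return RDM(self.values.copy(), self.ids, self.source, self.distance_name)

    @staticmethod
    def from_lower_triangle(
        vec: np.ndarray, ids, source: str = "model", distance_name: str = ""
    ) -> "RDM":
        """Inverse of :meth:`lower_triangle` (row-major strictly-lower order)."""
        n = len(ids)
        vec = np.asarray(vec, dtype=float)
        if vec.size != n * (n - 1) // 2:
            raise ValueError("vector length does not match id count")
        values = np.zeros((n, n))
        r, c = np.tril_indices(n, k=-1)
        values[r, c] = vec
        values[c, r] = vec
        return RDM(values, ids, source, distance_name)


@dataclass
class ResponseMatrix:
    """Per-participant stimulus x channel response amplitudes.

    Channels are voxels for fMRI beta patterns, or units for network feature
    matrices; values are unitless amplitudes.
    """

    values: np.ndarray
    stimulus_ids: tuple[str, ...]
    channel_ids: tuple[str, ...] | None = None
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.stimulus_ids = tuple(str(i) for i in self.stimulus_ids)
        if self.values.ndim != 2:
            raise ValueError("response matrix must be 2-D (stimuli x channels)")
        if self.values.shape[0] != len(self.stimulus_ids):
            raise ValueError("row count does not match stimulus_ids")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("need at least 2 stimuli and 2 channels")
        if self.channel_ids is not None:
            self.channel_ids = tuple(str(c) for c in self.channel_ids)
            if len(self.channel_ids) != self.values.shape[1]:
                raise ValueError("channel_ids does not match column count")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def correlation_distance_rdm(patterns: ResponseMatrix) -> RDM:
    """Build a neural/feature RDM using the 1 - r correlation distance.

    ``d(i, j) = 1 - Pearson r`` between the response patterns of stimuli *i*
    and *j*, giving dissimilarities in [0, 2].  A stimulus whose pattern is
    constant across channels has no defined correlation with anything; its
    entries are set to NaN and a warning is issued.
    """
    x = patterns.values
    sd = x.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    d = 1.0 - r
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant response row(s); "
            "their distances are undefined (NaN)",
            RuntimeWarning,
            stacklevel=2,
        )
        d[constant, :] = np.nan
        d[:, constant] = np.nan
    np.fill_diagonal(d, 0.0)
    # clip tiny negative values from floating-point round-off
    defined = ~np.isnan(d)
    d[defined] = np.clip(d[defined], 0.0, 2.0)
    return RDM(d, patterns.stimulus_ids, source="neural", distance_name="1-r")


def lower_triangle_vector(values: np.ndarray | RDM) -> np.ndarray:
    """Strictly-below-diagonal entries in deterministic row-major order.

    For a 3x3 matrix the order is (d21, d31, d32); the length is n(n-1)/2.
    """
    if isinstance(values, RDM):
        values = values.values
    values = np.asarray(values)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("input must be a square matrix")
    r, c = np.tril_indices(values.shape[0], k=-1)
    return values[r, c]


def _check_aligned(a: RDM, b: RDM) -> None:
    if a.ids != b.ids:
        raise ValueError("RDMs have mismatched stimulus ids or ordering")


def compare_rdms(
    a: RDM, b: RDM, method: str = "spearman"
) -> tuple[float, float]:
    """Rank-correlate two RDMs over their jointly defined lower-triangle pairs.

    Returns ``(rho, p)`` with a two-sided asymptotic p-value.  ``method`` may
    be ``"spearman"`` (default, the standard RSA comparison) or ``"pearson"``.
    """
    _check_aligned(a, b)
    va, vb = a.lower_triangle(), b.lower_triangle()
    ok = ~np.isnan(va) & ~np.isnan(vb)
    if ok.sum() < 3:
        raise ValueError("need at least 3 jointly defined pairs")
    va, vb = va[ok], vb[ok]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("an RDM lower triangle is constant; correlation undefined")
    if method == "spearman":
        rho, p = stats.spearmanr(va, vb)
    elif method == "pearson":
        rho, p = stats.pearsonr(va, vb)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


def noise_ceiling(rdms: list[RDM], method: str = "pearson") -> float:
    """Leave-one-out noise ceiling of a set of per-participant RDMs.

    Each participant's lower-triangle vector is correlated with the mean of
    all other participants' vectors; the coefficients are averaged.  This is
    the lower-bound style ceiling: the expected correlation an ideal model
    could reach given inter-participant variability.
    """
    if len(rdms) < 2:
        raise ValueError("noise ceiling needs at least 2 participants")
    for r in rdms[1:]:
        _check_aligned(rdms[0], r)
    mat = np.array([r.lower_triangle() for r in rdms])
    coefs = []
    for i in range(len(rdms)):
        others = np.delete(mat, i, axis=0)
        mean_others = np.nanmean(others, axis=0)
        vi = mat[i]
        ok = ~np.isnan(vi) & ~np.isnan(mean_others)
        if method == "pearson":
            coefs.append(stats.pearsonr(vi[ok], mean_others[ok])[0])
        elif method == "spearman":
            coefs.append(stats.spearmanr(vi[ok], mean_others[ok])[0])
        else:
            raise ValueError(f"unknown method {method!r}")
    return float(np.mean(coefs))


def group_average_rdm(rdms: list[RDM]) -> RDM:
    """Entrywise mean RDM over participants, missing-aware.

    An entry is the mean of the defined values across participants; an entry
    missing for every participant raises.
    """
    if not rdms:
        raise ValueError("no RDMs to average")
    for r in rdms[1:]:
        _check_aligned(rdms[0], r)
    stack = np.array([r.values for r in rdms])
    all_missing = np.isnan(stack).all(axis=0)
    if all_missing.any():
        raise ValueError("some entries are missing for all participants")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return RDM(
        mean, rdms[0].ids, source=rdms[0].source, distance_name=rdms[0].distance_name
    )


def _metric_stress1(coords: np.ndarray, d: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against raw dissimilarities."""
    from scipy.spatial.distance import pdist

    dist = pdist(coords)
    # pdist pair order is upper-triangle row-major; index d the same way
    iu = np.triu_indices(d.shape[0], k=1)
    delta = d[iu]
    denom = np.sum(dist**2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - delta) ** 2) / denom))


def mds_embed(
    rdm: RDM,
    dims: int = 2,
    seed: int | None = None,
    n_restarts: int = 8,
    metric: bool = False,
) -> tuple[np.ndarray, float]:
    """Embed an RDM in ``dims`` dimensions by MDS with stress-1 as criterion.

    Nonmetric by default (stress-1 is the nonmetric criterion, with
    disparities from isotonic regression); a classical-scaling solution
    seeds the first run and ``n_restarts - 1`` random restarts follow.
    Returns ``(coordinates, stress1)`` of the best run.  Distances exactly
    embeddable in ``dims`` dimensions give stress ~ 0 and recover the
    configuration up to rotation/reflection/scale.
    """
    d = np.asarray(rdm.values, dtype=float)
    if np.isnan(d).any():
        raise ValueError("MDS requires a complete RDM (no missing entries)")
    rng = np.random.default_rng(seed)

    def run(init: str):
        model = MDS(
            n_components=dims,
            metric_mds=metric,
            metric="precomputed",
            n_init=1,
            init=init,
            max_iter=500,
            eps=1e-9,
            random_state=int(rng.integers(2**31 - 1)),
            normalized_stress=not metric,
        )
        coords = model.fit_transform(d)
        if metric:
            stress = _metric_stress1(coords, d)
        else:
            # with normalized_stress=True sklearn's stress_ is already stress-1
            stress = float(model.stress_)
        return coords, stress

    best_coords, best_stress = run("classical_mds")
    for _ in range(max(0, n_restarts - 1)):
        coords, s = run("random")
        if s < best_stress:
            best_coords, best_stress = coords, s
    return best_coords, best_stress
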