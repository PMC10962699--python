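"""Commonality analysis: three-predictor variance partitioning of RDM
dissimilarities with a permutation significance test.

The full model regresses the group-averaged lower-triangle dissimilarities
on three model-RDM predictors by ordinary least squares.  Its R-squared is
decomposed into seven signed components - one unique share per predictor and
four common (shared) shares - by the standard weighting identities over the
R-squared values of all seven predictor subsets:

    U(a)    = R2_abc - R2_bc
    U(b)    = R2_abc - R2_ac
    U(c)    = R2_abc - R2_ab
    C(ab)   = R2_ac + R2_bc - R2_c - R2_abc
    C(ac)   = R2_ab + R2_bc - R2_b - R2_abc
    C(bc)   = R2_ab + R2_ac - R2_a - R2_abc
    C(abc)  = R2_a + R2_b + R2_c - R2_ab - R2_ac - R2_bc + R2_abc

The seven components sum to the full-model R-squared exactly; common
components may legitimately be negative (suppression).  Significance of the
full model comes from a permutation scheme in which each participant's
strictly-lower-triangular RDM rows are independently shuffled before
averaging and refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .rdm import RDM, group_average_rdm, lower_triangle_vector

__all__ = [
    "CommonalityResult",
    "PermutationResult",
    "fit_subset_r2",
    "partition_variance",
    "commonality_analysis",
    "permutation_test_full_model",
    "SUBSETS",
    "COMPONENTS",
]

SUBSETS = ("a", "b", "c", "ab", "ac", "bc", "abc")
COMPONENTS = ("U(a)", "U(b)", "U(c)", "C(ab)", "C(ac)", "C(bc)", "C(abc)")


def _r2(y: np.ndarray, x: np.ndarray) -> float:
    """R-squared of an intercept-included least-squares fit (least-norm
    solution under collinearity)."""
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValueError("dependent variable is constant; R2 undefined")
    return float(1.0 - np.sum(resid**2) / sst)


def fit_subset_r2(
    y: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> dict[str, float]:
    """OLS R-squared of every nonempty subset of three predictors.

    Returns a dict keyed 'a', 'b', 'c', 'ab', 'ac', 'bc', 'abc'.  All
    vectors must have equal length >= 5; a collinear full design is flagged
    with a warning (the least-norm fit still defines each R-squared).
    """
    y, a, b, c = (np.asarray(v, dtype=float).ravel() for v in (y, a, b, c))
    n = len(y)
    if not (len(a) == len(b) == len(c) == n):
        raise ValueError("y and predictors must have equal length")
    if n < 5:
        raise ValueError("need at least 5 observations")
    preds = {"a": a, "b": b, "c": c}
    for k, v in preds.items():
        if np.ptp(v) == 0:
            raise ValueError(f"predictor {k!r} is constant")
    full = np.column_stack([np.ones(n), a, b, c])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        warnings.warn(
            "collinear full design; subset R2 computed via least-norm fits",
            RuntimeWarning,
            stacklevel=2,
        )
    out = {}
    for s in SUBSETS:
        x = np.column_stack([preds[k] for k in s])
        out[s] = _r2(y, x)
    return out


@dataclass
class CommonalityResult:
    """Seven-way variance partition of a three-predictor regression.

    Attributes
    ----------
    r2_full : float
        R-squared of the full (a, b, c) model.
    components : dict
        Signed variance shares keyed 'U(a)', 'U(b)', 'U(c)', 'C(ab)',
        'C(ac)', 'C(bc)', 'C(abc)'; they sum to ``r2_full``.
    percent_of_explained : dict
        Components as percentages of the explained (not total) variance.
    predictor_names : tuple
        Display names substituted for a, b, c in ``summary``.
    """

    r2_full: float
    components: dict[str, float]
    percent_of_explained: dict[str, float]
    subset_r2: dict[str, float] = field(default_factory=dict)
    predictor_names: tuple[str, str, str] = ("a", "b", "c")

    def summary(self) -> str:
        na, nb, nc = self.predictor_names
        rename = {"a": na, "b": nb, "c": nc}

        def label(comp: str) -> str:
            inner = comp[comp.index("(") + 1 : -1]
            pretty = ",".join(rename[ch] for ch in inner)
            return f"{comp[0]}({pretty})"

        lines = [
            "Commonality analysis (3-predictor variance partition)",
            "=" * 56,
            f"Full-model R2: {self.r2_full:.4f}",
            "",
            f"{'component':<28}{'share':>10}{'% explained':>14}",
            "-" * 52,
        ]
        for comp in COMPONENTS:
            lines.append(
                f"{label(comp):<28}{self.components[comp]:>10.4f}"
                f"{self.percent_of_explained[comp]:>13.1f}%"
            )
        return "\n".join(lines)


def partition_variance(
    r2: dict[str, float],
    predictor_names: tuple[str, str, str] = ("a", "b", "c"),
) -> CommonalityResult:
    """Apply the seven-component weighting identities to subset R-squareds.

    Negative common components are legal (suppression) and reported as-is.
    """
    missing = set(SUBSETS) - set(r2)
    if missing:
        raise ValueError(f"missing subset R2 values: {sorted(missing)}")
    g = {k: float(r2[k]) for k in SUBSETS}
    comp = {
        "U(a)": g["abc"] - g["bc"],
        "U(b)": g["abc"] - g["ac"],
        "U(c)": g["abc"] - g["ab"],
        "C(ab)": g["ac"] + g["bc"] - g["c"] - g["abc"],
        "C(ac)": g["ab"] + g["bc"] - g["b"] - g["abc"],
        "C(bc)": g["ab"] + g["ac"] - g["a"] - g["abc"],
        "C(abc)": g["a"] + g["b"] + g["c"] - g["ab"] - g["ac"] - g["bc"] + g["abc"],
    }
    r2_full = g["abc"]
    if r2_full > 0:
        pct = {k: 100.0 * v / r2_full for k, v in comp.items()}
    else:
        pct = {k: float("nan") for k in comp}
    return CommonalityResult(
        r2_full=r2_full,
        components=comp,
        percent_of_explained=pct,
        subset_r2=g,
        predictor_names=predictor_names,
    )


def commonality_analysis(
    y: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    predictor_names: tuple[str, str, str] = ("a", "b", "c"),
) -> CommonalityResult:
    """Fit all predictor subsets and partition the full-model R-squared."""
    return partition_variance(fit_subset_r2(y, a, b, c), predictor_names)


def _shuffle_lower_triangle_rows(
    values: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Independently permute each row of the strictly-lower-triangular array
    and return the row-major vectorization."""
    n = values.shape[0]
    out = np.empty(n * (n - 1) // 2)
    pos = 0
    for i in range(1, n):
        row = values[i, :i]
        out[pos : pos + i] = row[rng.permutation(i)]
        pos += i
    return out


@dataclass
class PermutationResult:
    """Observed full-model R-squared and its permutation p-value."""

    observed_r2: float
    p_value: float
    n_perm: int
    n_exceed: int
    null_r2: np.ndarray | None = None

    @property
    def p_display(self) -> str:
        if self.n_exceed == 0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.p_value:g}"


def permutation_test_full_model(
    participant_rdms: list[RDM],
    predictors: tuple[RDM, RDM, RDM],
    n_perm: int = 1000,
    seed: int | None = None,
    scheme: str = "rows",
    keep_null: bool = False,
) -> PermutationResult:
    """Permutation test of the three-predictor full model on group-average RDMs.

    The observed statistic is the R-squared of the group-averaged
    lower-triangle dissimilarities regressed on the three predictor vectors.
    Under the null, each participant's strictly-lower-triangular RDM rows are
    independently shuffled (``scheme='rows'``; ``scheme='vector'`` permutes
    the whole lower-triangle vector instead), the shuffled vectors are
    averaged across participants, and the full model refitted; the p-value
    is the proportion of null R-squared values greater than the observed
    one.  Zero exceedances are reported as ``< 1/n_perm`` via
    :attr:`PermutationResult.p_display`.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(
            "n_perm < 100 gives a coarse p-value resolution",
            UserWarning,
            stacklevel=2,
        )
    if len(participant_rdms) < 2:
        raise ValueError("need at least 2 participants")
    if scheme not in ("rows", "vector"):
        raise ValueError("scheme must be 'rows' or 'vector'")
    pa, pb, pc = predictors
    for p in (pb, pc):
        if p.ids != pa.ids:
            raise ValueError("predictor RDMs have mismatched ids")
    for r in participant_rdms:
        if r.ids != pa.ids:
            raise ValueError("participant RDMs do not align with predictors")
    va = lower_triangle_vector(pa.values)
    vb = lower_triangle_vector(pb.values)
    vc = lower_triangle_vector(pc.values)
    avg = group_average_rdm(participant_rdms)
    y_obs = lower_triangle_vector(avg.values)
    if np.isnan(y_obs).any():
        raise ValueError("group-average RDM has missing pairs")
    design = np.column_stack([np.ones(len(y_obs)), va, vb, vc])

    def full_r2(y: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        sst = np.sum((y - y.mean()) ** 2)
        return float(1.0 - np.sum(resid**2) / sst)

    observed = full_r2(y_obs)
    rng = np.random.default_rng(seed)
    mats = [r.values for r in participant_rdms]
    null = np.empty(n_perm)
    for k in range(n_perm):
        acc = np.zeros(len(y_obs))
        for m in mats:
            if scheme == "rows":
                acc += _shuffle_lower_triangle_rows(m, rng)
            else:
                v = lower_triangle_vector(m)
                acc += v[rng.permutation(len(v))]
        null[k] = full_r2(acc / len(mats))
    n_exceed = int(np.sum(null > observed))
    return PermutationResult(
        observed_r2=observed,
        p_value=n_exceed / n_perm,
        n_perm=n_perm,
        n_exceed=n_exceed,
        null_r2=null if keep_null else None,
    )
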