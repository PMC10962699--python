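# Methods

This note documents the models and procedures rsakit implements, the
assumptions behind them, the defaults of the synthetic-data generators, and
the numerical choices made where the design was genuinely open.

## The stimulus design and model RDMs

The default design has 48 stimuli: six object types (food items, food tools,
other-directed tools, self-directed tools, manipulable non-tool objects,
animals) × 8 exemplars, with aspect ratio (elongated vs stubby) fully
counterbalanced — 4 of each within every type. Ordering is type-major,
aspect-ratio-minor, fixing a reproducible serialization of every matrix.

Two dummy-coded model RDMs are derived from it:

- the **object-type model** depends only on the superclass pair (food,
  artefact, animal), placing food intermediate in similarity between
  artefacts and animals: within-superclass 0, food↔artefact 1,
  animal↔anything 2. The numeric levels are a free parameter; only their
  rank order matters to any Spearman-based comparison, so any
  order-preserving relabeling gives identical results. Food–food pairs take
  level 0: food is one coherent group, and the model describes
  between-superclass distances only.
- the **shape model** is binary: 0 for same aspect ratio, 1 otherwise.

Counterbalancing makes the two models nearly orthogonal; with the default
design their lower-triangle Spearman ρ is −0.02.

## Triplet pipeline

Pair dissimilarity is the fraction of co-occurrence trials on which either
member of the pair was picked as odd. Pairs that never co-occur are reported
as missing (NaN), never silently zero; all downstream correlations use the
jointly defined pairs only (pairwise deletion — unbiased under random
splits, unlike imputation).

Quality control excludes a (participant, session) block when its median RT
falls below 200 ms or above 10 000 ms, or when it responded uniformly.
"Uniform" is checked both on the chosen stimulus and on the chosen response
position; either alone excludes, a deliberately conservative superset of the
ambiguous criterion. A single-trial session is trivially uniform and is
excluded.

Split-half reliability partitions trials (default) or whole sessions into
random halves, aggregates an RDM per half, Pearson-correlates the halves
over jointly defined pairs, averages over 1000 splits (configurable), and
applies the Spearman–Brown correction 2r/(1+r). Trials are the default
split unit because data collection assigns chunks to sessions, so
trial-level splits are the finest exchangeable unit; session-level splits
are available for sensitivity analysis.

A deliberate caveat: in the zero-noise limit the aggregated RDM is a
consistent but not exactly rank-preserving transform of the generating
matrix — a pair's aggregated value counts third stimuli k with
d(i,j) > min(d(i,k), d(j,k)), which depends on each pair's own set of
minima. Empirically the rank correlation with a generic tie-free truth rises
from ≈0.91 at 8 stimuli to ≈0.98 at 48, approaching 1 with the number of
stimuli; the test suite asserts this convergent behavior rather than exact
rank identity.

## Rating pipeline

Ratings are integers 1–7, one per participant per stimulus. Group error bars
are 95% normal CIs centered on the mean (±1.96·SEM). Reliability splits
participants (the only exchangeable unit, since each rates each stimulus
once). The action-rating PCA z-scores task profiles before decomposition:
the tasks share a 1–7 scale but differ in spread, so the correlation-matrix
convention is the appropriate one; covariance PCA is available by
`standardize=False`.

## RDM core

Neural and feature RDMs use the 1 − r Pearson correlation distance over
response patterns (range [0, 2]); a constant pattern has undefined
correlations and yields flagged NaN entries. RDM comparison is the Spearman
rank correlation of lower-triangle vectors (row-major strictly-below-diagonal
order), invariant to any monotone transform of either RDM.

The noise ceiling is the leave-one-out lower-bound variant: each
participant's lower-triangle vector is Pearson-correlated with the mean of
the others', and the coefficients are averaged. The upper-bound variant
(correlating with the mean including the left-out participant) is not
implemented, as only the lower-bound style is used by the analyses this
package supports. Group inference on RDM correlations uses t-tests across
participants' coefficients; raw coefficients by default with Fisher-z as a
caller-side option, since the two differ negligibly at the coefficient
magnitudes involved.

MDS is nonmetric with stress-1 as the criterion (the nonmetric criterion of
the classical MDS tool family), run through scikit-learn's SMACOF with a
classical-scaling (Torgerson) initialization plus 7 seeded random restarts;
the best-stress solution is returned. Exactly embeddable distances give
stress ≈ 0 and recover the configuration up to similarity transform. Metric
MDS is available via `metric=True`, reporting Kruskal stress-1 of the raw
configuration.

## ROI definition and univariate statistics

Clustering uses 18-connectivity — face and edge neighbors, corners excluded
(`scipy.ndimage.label` with a connectivity-2 structuring element). ROI
definition walks a descending p-threshold ladder (0.001, 0.005, 0.01, 0.05 by
default): at each threshold, suprathreshold voxels inside the anatomical
mask are clustered and clusters under 40 voxels dropped; the first threshold
with survivors defines the ROI; if none succeeds, no ROI is created.
Clustering is applied before counting at every fallback step ("cluster then
count"). "Convolved with the mask" is implemented as set intersection. The
top-N variant ranks voxels by the contrast statistic without clustering,
breaking ties by linear voxel index for run-to-run determinism.

Univariate analyses average betas over ROI voxels, then over exemplars for
coarser groupings, and compare conditions with paired two-sided t-tests
(uncorrected p, matching the convention of reporting individual contrasts;
a Holm flag is a caller-side choice). Rating–response correlations are
per-participant Pearson coefficients tested against zero with a one-sample
two-sided t-test.

## Overlap analysis

Thresholded overlap applies p < 0.05 and 40-voxel clustering to each map
within the mask, then computes the Jaccard index and the two unique
fractions (all three sum to 1 over a nonempty union). A participant whose
thresholded map is empty has *undefined* overlap and is excluded from group
summaries rather than scored 0 — mirroring the reduced group sizes such
exclusions produce. The top-N curve uses no clustering, per its definition.
The same face+edge connectivity is used here as in ROI definition.

## Commonality analysis

All seven predictor-subset regressions are ordinary least squares with an
intercept, on raw (unranked) predictor vectors. The seven components follow
the standard three-predictor weighting identities and sum to the full-model
R² exactly (an algebraic identity, tested to 1e-10 over random inputs);
negative common components are legal (suppression) and reported as-is.

The permutation null independently shuffles each row of every participant's
strictly-lower-triangular RDM (rows of length 1..n−1), averages the
shuffled vectors across participants, and refits the full model; p is the
proportion of null R² values greater than the observed one. Because the
row-shuffle wording is ambiguous for a ragged triangular array, a
whole-vector permutation scheme is provided as a sensitivity option
(`scheme="vector"`). Zero exceedances are reported as "< 1/n_perm", the
standard permutation convention, rather than p = 0.

## Synthetic-data generators

The generators define the study conditions every end-to-end test runs under:

- **Ground truth**: `1.0 × type model + 0.3 × shape model`, rescaled to
  [0, 1]. The type-dominant mixture reflects behavioral RDMs in which the
  object-type structure is the primary signal with a weaker shape
  contribution.
- **Triplet choices**: the oddness score of a triplet member is the sum of
  its truth dissimilarities to the other two; choices are softmax over
  oddness at temperature 0.05 (near-deterministic but noisy), with a 2%
  lapse rate of uniform guessing — a simple Luce-style choice rule
  consistent with odd-one-out behavior. Reaction times are log-normal with
  configurable median (800 ms default); only the median matters to the QC
  paths.
- **Ratings**: truth + participant offset (sd = noise/2) + trial noise,
  rounded and clipped into 1..7.
- **Voxel patterns**: 12 participants × 200 voxels by default; each voxel's
  profile across stimuli is multivariate normal with covariance 1 − truth
  (projected to the nearest PSD matrix by eigenvalue clipping, which
  guarantees a valid sampling distribution for arbitrary truth RDMs), plus
  independent N(0, 0.6) measurement noise.
- **Stat maps**: two Gaussian-profile blobs (peak 6, σ = 3 voxels) on a
  24³ grid, displaced along one axis; p-values are upper-tail normal
  probabilities of the statistic, and the noise-free suprathreshold Jaccard
  is returned as the construction's true overlap.

What the generators deliberately do **not** emulate: spatial autocorrelation
beyond the Gaussian blob profile, hemodynamic structure, inter-regional
heterogeneity, or non-stationary participant behavior. Passing tests
therefore demonstrate the correctness and calibration of the analysis chain
under its own assumptions, not robustness to real-data violations of them.

## Problem sizes and determinism

End-to-end checks use one full triplet enumeration (17 296 trials), 12
simulated participants at 200 voxels, 20 replicates for the
commonality win-rate, and 50 null replicates at 200 permutations for the
type-I calibration — sizes chosen so the whole suite and the acceptance
script each complete in well under a quarter hour on a single core while
leaving the Monte Carlo error of every assertion comfortably inside its
margin. Every stochastic routine takes an explicit seed; the acceptance
script derives all sub-seeds from one `--seed` via `numpy.random.SeedSequence`.

## Known limitations

- Only the three-predictor commonality case is implemented (the seven-way
  partition); more predictors would need the general 2^k − 1 weighting
  table.
- `aggregate_rdm` treats every trial as exchangeable; it does not model
  participant-level random effects.
- NIfTI handling assumes congruent grids; no resampling or registration is
  provided (inputs are expected in a common space already).
- The adaptive ROI rule returns the first threshold at which *any* cluster
  survives; it does not search for the threshold maximizing ROI size.
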