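# rsakit

Behavioral and neural **representational similarity analysis** (RSA) for
category-selectivity studies — in particular, designs that ask whether two
stimulus classes (e.g. graspable food items and tools) are represented
similarly in visual cortex.

The toolkit covers the full analysis chain of such a study:

- **Odd-one-out triplet judgments** → representational dissimilarity matrices
  (RDMs). A participant sees three stimuli and picks the odd one out; the
  dissimilarity of a pair (i, j) is the fraction of trials containing both on
  which either *i* or *j* was picked. Includes triplet enumeration and
  chunking (C(48, 3) = 17 296 triplets → 412 chunks of 42), session-level
  quality control (uniform responding, median RT < 200 ms or > 10 000 ms),
  and split-half reliability with the Spearman–Brown correction
  r* = 2r / (1 + r).
- **Likert rating tasks** (1–7): per-stimulus means with 95% normal CIs,
  participant split-half reliability, between-task correlations, and a PCA
  of the stimulus × task matrix of mean action ratings.
- **RDM core**: the 1 − r correlation distance over response patterns,
  Spearman comparison of lower-triangle vectors, missing-aware group
  averaging, the leave-one-participant-out noise ceiling, and nonmetric MDS
  with stress-1.
- **ROI definition and univariate statistics**: adaptive-threshold ROIs
  (p-threshold ladder 0.001 → 0.05, 40-voxel minimum clusters under
  face+edge connectivity), top-N most-selective voxels, ROI mean responses,
  and paired / one-sample t-tests.
- **Map overlap**: the Jaccard index |F ∩ T| / |F ∪ T| of two thresholded
  selectivity maps, the unique fractions of each map, and top-N overlap
  curves (50–500 voxels in steps of 50).
- **Commonality analysis**: three-predictor variance partitioning of
  group-averaged RDM dissimilarities into seven unique/common R² components,
  with a permutation test that independently shuffles the rows of each
  participant's lower-triangular RDM.
- **Synthetic data** for every stage: softmax (Luce-choice) triplet
  responders over a latent RDM, noisy Likert raters, voxel patterns whose
  correlation structure follows a target RDM, and Gaussian-blob statistical
  map pairs with a controllable true overlap — so the whole pipeline is
  testable end to end with no data download.

## Worked example

A complete synthetic study under the default conditions (48 stimuli = 6
object types × 8 exemplars, counterbalanced aspect ratio; ground truth
dominated by the object-type model; one full triplet enumeration; 12
simulated participants with 200 voxels each):

```python
import numpy as np
from rsakit import (
    GeneratorConfig, make_truth_rdm, simulate_triplet_responses, qc_filter,
    aggregate_rdm, split_half_reliability, compare_rdms, make_type_model_rdm,
    make_shape_model_rdm, simulate_subject_patterns, correlation_distance_rdm,
    group_average_rdm, noise_ceiling, commonality_analysis,
    permutation_test_full_model, lower_triangle_vector, RDM,
)

cfg = GeneratorConfig(seed=0)
truth = make_truth_rdm(cfg)

trials = simulate_triplet_responses(truth, cfg, full_enumeration=True)
kept, report = qc_filter(trials)
behav, _ = aggregate_rdm(kept)
type_rdm = make_type_model_rdm(cfg.design)
shape_rdm = make_shape_model_rdm(cfg.design)
print(f"trials kept after QC: {kept.n_trials} (excluded sessions: {report.n_excluded_sessions})")
print(f"split-half reliability (Spearman-Brown): {split_half_reliability(kept, n_splits=100, seed=0):.2f}")
print(f"behavioral RDM vs object-type model: rho = {compare_rdms(behav, type_rdm)[0]:.2f}")
print(f"behavioral RDM vs shape model:       rho = {compare_rdms(behav, shape_rdm)[0]:.2f}")
print(f"type model vs shape model:           rho = {compare_rdms(type_rdm, shape_rdm)[0]:.2f}")

patterns = simulate_subject_patterns(truth, cfg)
rdms = [correlation_distance_rdm(p) for p in patterns.values()]
avg = group_average_rdm(rdms)
print(f"group-average neural RDM vs truth:   rho = {compare_rdms(avg, truth)[0]:.2f}")
print(f"noise ceiling (leave-one-out):       {noise_ceiling(rdms):.2f}")

rng = np.random.default_rng(1)
distractor = RDM.from_lower_triangle(rng.random(1128), truth.ids)
res = commonality_analysis(
    lower_triangle_vector(avg.values),
    lower_triangle_vector(type_rdm.values),
    lower_triangle_vector(shape_rdm.values),
    distractor.lower_triangle(),
    predictor_names=("type", "shape", "distractor"),
)
print(res.summary())
perm = permutation_test_full_model(rdms, (type_rdm, shape_rdm, distractor),
                                   n_perm=1000, seed=2)
print(f"permutation p (1000 shuffles): {perm.p_display}")
```

which prints:

```
trials kept after QC: 17296 (excluded sessions: 0)
split-half reliability (Spearman-Brown): 0.97
behavioral RDM vs object-type model: rho = 0.93
behavioral RDM vs shape model:       rho = 0.15
type model vs shape model:           rho = -0.02
group-average neural RDM vs truth:   rho = 0.98
noise ceiling (leave-one-out):       0.99

Commonality analysis (3-predictor variance partition)
========================================================
Full-model R2: 0.9983

component                        share   % explained
----------------------------------------------------
U(type)                         0.9770         97.9%
U(shape)                        0.0271          2.7%
U(distractor)                   0.0000          0.0%
C(type,shape)                  -0.0060         -0.6%
C(type,distractor)              0.0002          0.0%
C(shape,distractor)             0.0000          0.0%
C(type,shape,distractor)       -0.0000         -0.0%

permutation p (1000 shuffles): < 0.001
```

Reading the output: the aggregated behavioral RDM tracks the object-type
model far more than the shape model (the two models themselves are nearly
orthogonal by design, ρ = −0.02); the group-average neural RDM recovers the
generating structure close to the noise ceiling; and the commonality
partition attributes essentially all explained variance uniquely to the
generating (object-type) predictor, with the permutation test at its
resolution floor.

There is also a thin CLI mirroring the pipeline stages — see
`rsakit --help` (`triplets`, `ratings`, `rdm`, `roi`, `overlap`,
`commonality`, `simulate`).

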