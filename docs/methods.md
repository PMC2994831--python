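# Methods

This note documents the models, algorithms, parameter choices and
numerical conventions implemented in `micmap`, and what the simulation
results do and do not establish.

## The mapping problem

A linear decoder trained on whole-brain multi-voxel patterns assigns each
voxel a discriminative weight, and thresholding |w| yields a map of
"informative voxels" (MIV). Such maps are unstable: with limited samples
the weight estimates are noisy, so the voxels surviving a threshold change
from one cross-validation fold to the next. `micmap` interposes a
spatial aggregation step — rank *clusters* of voxels with similar response
profiles rather than single voxels — so that selection operates on fewer,
better-estimated features whose spatial support is coherent by
construction.

## Homogeneous-cluster parcellation

Competitive region growing on the raw (unshifted, unaveraged) time
series. Every masked voxel starts as a candidate cluster. The similarity
between adjacent clusters is the mean pairwise Pearson correlation over
all cross pairs of member voxels; it is computed exactly through the
identity

    mean_{v∈C, w∈D} r(x_v, x_w) = ⟨Σ_C z, Σ_D z⟩ / (#C·#D)

where z_v is the centered, unit-norm time series of voxel v (a constant
voxel maps to the zero vector, so its correlations are 0 and it never
attracts merges). Each sweep finds all pairs of adjacent clusters that are
mutual nearest neighbours — ties in the argmax break toward the lowest
cluster id, making the procedure fully deterministic — and merges them
simultaneously. A merged cluster whose size reaches the threshold Ts is
finalized; hence every finished cluster has between Ts and 2(Ts−1)
voxels. Candidates left when no mutual pair remains are excluded
(typically ~5% of the brain at Ts = 15). Adjacency defaults to
face-connectivity (6 neighbours); 26-connectivity is available.

The parcellation is computed **once per dataset** from the full raw
series and shared across cross-validation folds. It uses no condition
labels, so this leaks no information into the supervised stages; sharing
the cluster frame across folds is also what makes cluster-level mapping
stable (recomputing it per fold, available as `partition_scope="fold"`,
fragments the cross-fold overlap of selected sets and erases most of the
robustness advantage).

A non-adaptive baseline, `cubic_partition`, tiles the grid with
rectangular blocks (e.g. 3×3×2 = 18 voxels); blocks half-full or less
with masked voxels are excluded.

## Within-cluster summarization

* **uMIC** — the spatial mean of the cluster's voxels: appropriate if
  member responses were i.i.d., and deliberately destructive of
  voxel-scale pattern structure (its poor performance is informative).
* **mMIC** — the two-class Gaussian Naive Bayes log-odds with per-voxel,
  per-class means and maximum-likelihood variances fitted on training
  samples only. Variances are floored at `1e-8 × (mean training variance
  + 1e-12)` per fit to avoid infinities for degenerate voxels. Class
  priors come from training counts (zero for the balanced designs here,
  kept for generality). Positive discriminants favour the first class of
  the sorted label set. Training summaries are in-sample by design;
  cross-validated inner summaries were evaluated and performed worse as
  ranking features (see Design decisions).

## Ranking and selection

A soft-margin linear SVM (objective ½‖w‖² + C·Σ hinge; C = 1, features
unstandardized — both deliberate, see below) is trained on cluster
summaries (MIC) or voxel patterns (MIV). Feature informativeness is
|w_j|, ties breaking toward lower feature indices. Cluster weights are
projected to voxels (all members inherit the cluster's |w|; excluded
voxels get 0). Voxel counts at which maps are evaluated follow a
ten-level geometric progression, by default 100 … 3844 with ratio
(3844/100)^(1/9) ≈ 1.5. At a level of n voxels, MIC admits whole clusters
in rank order and fills the boundary cluster partially (ascending voxel
index) so MIC and MIV are compared at identical voxel counts; the
per-level classifier for MIC is retrained on the summaries of every
cluster contributing at least one selected voxel.

## Evaluation

Runs are dealt round-robin into k = 4 folds after a seeded shuffle; each
fold trains on 3/4 of the runs and tests on the rest, and the whole
procedure can be repeated with fresh shuffles (10 repetitions at study
scale; fewer at desk scale — the per-(repetition, level) robustness grid
is complete, so the two possible averaging orders coincide). Patterns are
block averages of the series shifted by 3 volumes (6 s hemodynamic
delay); shifted volumes never cross run boundaries (truncation with a
warning). Metrics: predictive accuracy per feature level; maximum
accuracy across levels; robustness = mean pairwise Jaccard overlap of the
voxel sets selected across folds (empty/empty pairs count 1); and, when
ground truth exists, ROC/AUC of the weight map against the
informative-voxel mask (thresholds sweep distinct weight values; the area
equals the normalized Mann–Whitney U statistic, which the tests verify).

## The simulator

The generator emulates a two-condition blocked experiment: 32×32×5 grid,
3×3×4 mm voxels, TR 2 s, eight runs; each run holds three 32-s blocks per
condition in seeded random order, separated by 16-s fixations (152
volumes per run; 8×3 block-averaged samples per condition). Two
informative regions are grown as random connected shapes of exact size
(15/30/60/120 voxels each); each condition receives an independent
standard-Gaussian amplitude per informative voxel, and both conditions
pattern both regions. Signals are the condition boxcars convolved with a
unit-peak double-gamma HRF (response delay 6 s, undershoot 16 s,
dispersions 1, undershoot ratio 1/6; peak of the sampled kernel at ~6 s
for TR 2 s). Noise is spatiotemporal Gaussian white noise smoothed
spatially with a 4-mm-FWHM kernel (per-axis sigma = FWHM/2.3548 divided by
the voxel dimension). The contrast-to-noise ratio is defined as the
spatial mean over informative voxels of the temporal maximum absolute
signal, divided by the pooled temporal SD of the *post-smoothing* noise
(√ of the voxel-mean temporal variance); because this ratio is linear in
the signal scale, one analytic rescaling calibrates it exactly. All
randomness derives from a single master seed through named substreams
(block order, placement, pattern, noise), so each component is
independently reproducible.

What the simulator does **not** model: temporal noise autocorrelation,
scanner drift, motion, physiological noise, event-related designs, more
than two conditions, or anatomically realistic gray-matter geometry.
Consequences worth knowing: with temporally white noise, block averaging
over 16 volumes attenuates noise fourfold, so even CNR 0.05 retains weak
decodability (maximum cross-validated accuracy ≈ 0.58–0.61 rather than
exactly chance — the desk-scale maximum-over-levels statistic also
carries a small upward selection bias); and because the signal variance
fraction in the raw series is ≲2% at every CNR level used, the
parcellation is driven by the smoothed-noise correlation structure, not
by the signal. Passing the simulation tests therefore demonstrates the
pipeline's statistical machinery and the cluster-versus-voxel stability
trade-off, not performance on physiological noise.

## Design decisions

* **C = 1, no feature standardization.** The SVM regularization level is
  a free parameter here; sensitivity checks (C = 1 vs 100) left every
  reported metric unchanged at these data scales. Standardizing features
  before the ranking SVM was evaluated and sharply *degraded* mMIC
  mapping: with unstandardized features the weight magnitude inherits the
  summary's scale, and informative clusters — whose discriminants
  separate more strongly — are exactly the large-scale features.
* **In-sample training summaries.** Computing the training-side GNB
  discriminants by inner leave-one-run-out CV (so uninformative clusters
  yield chance-level features) was evaluated and performed worse on both
  AUC and robustness; the straightforward in-sample summaries are kept.
* **Dataset-scope parcellation** (see above); per-fold scope available.
* **Orientation conventions.** SVM decision ties map to the positive
  (larger) class label; GNB discriminants favour the first (smaller)
  class label when positive. Both are documented determinism choices with
  no effect on |w| ranking or accuracy.
* **Desk-scale problem sizes.** The test suite and the acceptance script
  use the full 32×32×5 grid with size-60 regions and Ts = 15, 4-fold CV
  with 1–3 repetitions and 3–5 seeds per condition — the same design as
  the study settings with fewer Monte-Carlo repetitions.

## Known limitations

* At CNR 0.10 the seed-averaged AUC of mMIC trails MIV (≈0.62 vs 0.65
  over five seeds) and their robustness is statistically tied; at
  CNR 0.20 mMIC matches MIV on AUC and clearly beats it on robustness
  (≈0.42 vs 0.34). The low-contrast gap traces to the ranking stage: an
  oracle that ranks clusters by their true informative fraction reaches
  AUC ≈ 0.95 with the same parcellation, so the partition is not the
  bottleneck — with 36 training samples, in-sample GNB summaries of
  every ~20-voxel cluster separate the classes by overfitting alone, and
  the informative clusters' extra separation is a small increment at weak
  contrast. The alternatives evaluated (inner-CV summaries,
  standardization) made this worse, so the limitation is reported rather
  than masked.
* `region_grow` is exact but quadratic-ish in neighbours per sweep;
  ~5000 voxels × ~1200 volumes partitions in about a second, but very
  large masks (whole-brain at 2 mm) would need a coarser similarity
  cache.
* The robustness metric compares voxel *sets* only; it is blind to how
  far a displaced selection moved.
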