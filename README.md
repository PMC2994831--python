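# micmap — mapping informative clusters for fMRI MVPA

Multivariate pattern analysis (MVPA) decodes experimental conditions from
joint activity patterns across voxels, but when the same machinery is used
for *brain mapping* — asking *where* the discriminative information lives —
the selected voxels jump around between cross-validation folds, making the
maps hard to interpret. `micmap` implements a hierarchical alternative:
instead of ranking single voxels, it ranks spatially coherent **homogeneous
clusters**, trading none of the discriminative power for markedly more
stable maps.

The pipeline:

1. **Parcellation.** Competitive region growing on raw BOLD time series.
   The similarity between adjacent clusters *C*, *D* is the mean pairwise
   Pearson correlation
   `s(C, D) = (1 / #C·#D) Σ_{v∈C} Σ_{w∈D} r(x_v, x_w)`;
   mutual nearest neighbours merge simultaneously each sweep, and a cluster
   is finalized once its size reaches a threshold *Ts* (sizes end up in
   `[Ts, 2(Ts−1)]`).
2. **Within-cluster summarization.** Each cluster's multi-voxel pattern is
   collapsed to one number: its spatial mean (**uMIC**), or the two-class
   Gaussian-Naive-Bayes discriminant (**mMIC**)
   `g_H(x) = log P(c1)/P(c2) + Σ_{v∈H} [log N(x_v; μ_v1, σ²_v1) − log N(x_v; μ_v2, σ²_v2)]`
   with per-voxel class-conditional means and variances fitted on training
   samples only.
3. **Multivariate ranking.** A soft-margin linear SVM
   (`min ½‖w‖² + C Σ hinge`) is trained on the cluster summaries (or on raw
   voxel patterns for the baseline **MIV**); each feature's informativeness
   is `|w_j|`, projected back to voxel space.
4. **Evaluation.** Top-ranked voxels are selected at ten geometric feature
   levels (100, 150, 225, …, 3844); per level a classifier retrained on the
   selection is scored on held-out runs. Mapping **robustness** is the mean
   cross-fold Jaccard overlap `|S_i ∩ S_j| / |S_i ∪ S_j|` of selected sets,
   and on simulated data weight maps are scored by **ROC/AUC** against the
   ground-truth informative voxels.

The package ships the matching **block-design BOLD simulator**: a 32×32×5
grid (3×3×4 mm voxels, TR 2 s), eight runs of three 32-s blocks per
condition separated by 16-s fixations, condition-specific Gaussian spatial
patterns confined to two irregular connected regions, double-gamma HRF
convolution, and spatially smoothed Gaussian noise with the signal rescaled
so the contrast-to-noise ratio (spatial mean of the peak absolute signal
over the temporal noise SD) hits the requested target exactly.

## Worked example

`python examples/map_informative_clusters.py` simulates one dataset at
CNR 0.20 (two 60-voxel informative regions) and runs the three pipelines
under run-wise 4-fold cross-validation:

```
method  max acc  mean AUC  robustness
  mmic    1.000     0.801       0.504
  umic    0.792     0.636       0.369
   miv    1.000     0.792       0.343
```

mMIC decodes as well as voxel-wise MIV (max accuracy 1.0) and detects the
informative voxels slightly better (AUC), while its maps are far more
stable across folds (robustness 0.50 vs 0.34). Mean-summarized clusters
(uMIC) wash out the voxel-scale pattern and perform worst — the reason the
multivariate summary matters. The other example scripts demonstrate the
simulator (`simulate_block_design.py`), the parcellation
(`partition_homogeneous_clusters.py`) and the set-similarity metric
(`robustness_and_overlap.py`).

A thin CLI mirrors the library for shell use:

```bash
micmap simulate --seed 1 --out data/
micmap partition --bold data/bold.nii.gz --mask mask.nii.gz --ts 15 --out part.json
micmap evaluate --method mmic --bold data/bold.nii.gz --mask mask.nii.gz \
    --design data/design.tsv --truth data/truth_mask.nii.gz --out results/
```

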