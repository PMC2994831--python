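"""Map informative clusters (mMIC) versus informative voxels (MIV).

Runs the full cross-validated pipelines on one simulated dataset at
CNR 0.20: per fold, features are ranked by linear-SVM weight magnitude
(clusters summarized by their GNB discriminant for mMIC), the top voxels
are selected at ten geometric feature levels, and a classifier retrained
on the selection is scored on held-out runs.  Weight maps are scored by
ROC/AUC against the ground-truth informative voxels, and mapping
robustness is the mean cross-fold Jaccard overlap of selected sets.
"""

from micmap import SimulationConfig, build_block_design, run_pipeline, simulate_dataset

config = SimulationConfig(seed=11, cnr=0.20, region_size_voxels=60)
ts, truth = simulate_dataset(config)
design = build_block_design(config)

print(f"{'method':>6} {'max acc':>8} {'mean AUC':>9} {'robustness':>11}")
for method in ("mmic", "umic", "miv"):
    res = run_pipeline(
        method, ts, design, size_threshold=15, n_folds=4, n_reps=1, seed=1,
        truth_mask=truth.informative_mask,
    )
    print(f"{method:>6} {res.max_accuracy:8.3f} {res.mean_auc:9.3f} "
          f"{res.mean_robustness:11.3f}")

print(
    "\nmax acc: best cross-validated decoding accuracy over the ten feature\n"
    "levels; AUC: how well the weight map detects the preset informative\n"
    "voxels; robustness: cross-fold stability of the selected voxel sets.\n"
    "Cluster-level mapping (mmic) trades little or no accuracy for markedly\n"
    "more stable maps than voxel-level ranking (miv); mean-summarized\n"
    "clusters (umic) wash out the voxel-scale pattern and decode worst."
)
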