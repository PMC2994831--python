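"""Within-cluster summarization: collapse each cluster's multi-voxel
pattern to a single value.

Two summaries are provided.  The univariate summary (uMIC) is the spatial
mean over the cluster's voxels, appropriate if within-cluster responses
are i.i.d.  The multivariate summary (mMIC) relaxes the identical-
distribution assumption: a two-class Gaussian Naive Bayes (GNB) model is
fitted per cluster on training samples, and the cluster's summary value
for a pattern is the GNB discriminant — the class log-odds

    log P(c1)/P(c2) + sum_v [ log N(x_v; mu_v1, s2_v1) - log N(x_v; mu_v2, s2_v2) ]

with per-voxel class-conditional means and (floored, maximum-likelihood)
variances.  Positive values favour class 1, the first label of the sorted
label set.  The summaries of all clusters form a multi-cluster pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .partition import ClusterPartition
from .preprocess import PatternSet

#: relative variance floor, scaled by the mean training variance of the fit
VAR_FLOOR_REL = 1e-8


@dataclass
class GNBClusterModel:
    """Per-cluster two-class Gaussian Naive Bayes parameters.

    ``means``/``variances`` have shape (2, n cluster voxels), class 1
    first; ``voxel_indices`` map columns to the dataset's voxel axis;
    ``classes`` are the two label values in sorted order.
    """

    voxel_indices: np.ndarray
    classes: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_prior_ratio: float

    def __post_init__(self):
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")


def _class_split(labels: np.ndarray):
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes!r}")
    return classes, labels == classes[0]


def _variance_floor(raw_var: np.ndarray) -> float:
    return VAR_FLOOR_REL * (float(np.mean(raw_var)) + 1e-12)


def fit_gnb(train: PatternSet, cluster) -> GNBClusterModel:
    """Fit per-voxel class-conditional Gaussians on training samples only.

    Means and variances are the per-class sample mean and biased (ML)
    variance of each cluster voxel's responses; variances are floored at
    a small fraction of the fit's mean variance.  Class priors come from
    training counts.
    """
    cluster = np.asarray(list(cluster), dtype=int)
    cols = _feature_columns(train, cluster)
    classes, is_c1 = _class_split(train.labels)
    if is_c1.sum() < 2 or (~is_c1).sum() < 2:
        raise ValueError("need at least 2 training samples per class")
    x1, x2 = train.matrix[is_c1][:, cols], train.matrix[~is_c1][:, cols]
    means = np.stack([x1.mean(axis=0), x2.mean(axis=0)])
    raw_var = np.stack([x1.var(axis=0), x2.var(axis=0)])
    variances = np.maximum(raw_var, _variance_floor(raw_var))
    log_prior_ratio = float(np.log(is_c1.sum() / (~is_c1).sum()))
    return GNBClusterModel(cluster, classes, means, variances, log_prior_ratio)


def gnb_discriminant(model: GNBClusterModel, pattern) -> float:
    """GNB log-odds of one within-cluster pattern; positive favours class 1."""
    x = np.asarray(pattern, dtype=float)
    if x.shape != (model.voxel_indices.size,):
        raise ValueError(
            f"pattern must cover the model's {model.voxel_indices.size} voxels"
        )
    logn = -0.5 * (
        np.log(2 * np.pi * model.variances) + (x - model.means) ** 2 / model.variances
    )
    return float(model.log_prior_ratio + (logn[0] - logn[1]).sum())


def _feature_columns(patterns: PatternSet, voxel_indices: np.ndarray) -> np.ndarray:
    """Columns of a voxel PatternSet corresponding to given voxel indices."""
    if patterns.feature_kind != "voxel":
        raise ValueError("expected a voxel-level PatternSet")
    pos = {int(v): c for c, v in enumerate(patterns.feature_map)}
    try:
        return np.array([pos[int(v)] for v in voxel_indices], dtype=int)
    except KeyError as e:
        raise ValueError(f"cluster voxel {e} missing from the pattern set") from e


def summarize_umic(patterns: PatternSet, part: ClusterPartition) -> PatternSet:
    """Univariate summary: entry (sample, cluster) = spatial mean over the cluster."""
    cols = np.zeros((patterns.n_samples, part.n_clusters))
    for cid, cluster in enumerate(part.clusters):
        if len(cluster) == 0:
            raise ValueError(f"cluster {cid} is empty")
        cols[:, cid] = patterns.matrix[:, _feature_columns(patterns, cluster)].mean(axis=1)
    return PatternSet(
        cols,
        patterns.labels,
        patterns.sample_runs,
        feature_kind="cluster",
        feature_map=np.arange(part.n_clusters),
    )


def summarize_mmic(train: PatternSet, test: PatternSet, part: ClusterPartition):
    """Multivariate summary: per-cluster GNB discriminants.

    One GNB model per cluster is fitted on ``train`` only; both outputs
    are discriminants under those models (the test set never influences
    the fit).  Returns (train summary, test summary) as cluster
    PatternSets.
    """
    if not np.array_equal(train.feature_map, test.feature_map):
        raise ValueError("train and test must share the same feature_map")
    out_train = np.zeros((train.n_samples, part.n_clusters))
    out_test = np.zeros((test.n_samples, part.n_clusters))
    classes, is_c1 = _class_split(train.labels)
    if is_c1.sum() < 2 or (~is_c1).sum() < 2:
        raise ValueError("need at least 2 training samples per class")
    log_prior = float(np.log(is_c1.sum() / (~is_c1).sum()))

    # per-voxel params over all columns at once; per-cluster variance floor
    x1, x2 = train.matrix[is_c1], train.matrix[~is_c1]
    mu = np.stack([x1.mean(axis=0), x2.mean(axis=0)])
    raw_var = np.stack([x1.var(axis=0), x2.var(axis=0)])

    for cid, cluster in enumerate(part.clusters):
        cols = _feature_columns(train, cluster)
        var = np.maximum(raw_var[:, cols], _variance_floor(raw_var[:, cols]))
        m = mu[:, cols]
        for out, mat in ((out_train, train.matrix), (out_test, test.matrix)):
            x = mat[:, cols]
            logn = -0.5 * (
                np.log(2 * np.pi * var)[None, :, :]
                + (x[:, None, :] - m[None, :, :]) ** 2 / var[None, :, :]
            )
            out[:, cid] = log_prior + (logn[:, 0, :] - logn[:, 1, :]).sum(axis=1)

    mk = lambda p, out: PatternSet(  # noqa: E731
        out, p.labels, p.sample_runs, feature_kind="cluster",
        feature_map=np.arange(part.n_clusters),
    )
    return mk(train, out_train), mk(test, out_test)
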