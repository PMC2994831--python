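"""Linear-SVM weight ranking of features and selection of informative
voxel sets at geometric feature levels.

A soft-margin linear SVM (objective (1/2)||w||^2 + C sum hinge) is trained
on voxel patterns (MIV) or on cluster summaries (MIC); each feature's
discriminative contribution is the absolute value |w_j| of its weight.
Weights are projected to voxel space as a :class:`WeightMap` — under MIC
every voxel of a cluster inherits the cluster's weight — and the
top-ranked voxels are selected at a geometric progression of voxel counts
(100, 150, 225, ..., 3844 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .partition import ClusterPartition
from .preprocess import PatternSet


@dataclass
class LinearSVMModel:
    """Trained linear SVM: decision value w.x + b; sign gives the label.

    ``classes`` are the two label values in sorted order; a positive (or
    zero) decision value maps to ``classes[1]``, matching the y = +1
    convention for +/-1 labels.
    """

    weights: np.ndarray
    bias: float
    C: float
    classes: np.ndarray

    @property
    def n_features(self) -> int:
        return self.weights.size


def train_linear_svm(patterns, labels, C: float = 1.0) -> LinearSVMModel:
    """Fit the soft-margin linear SVM on a samples x features matrix."""
    X = np.asarray(getattr(patterns, "matrix", patterns), dtype=float)
    y = np.asarray(labels)
    if C <= 0:
        raise ValueError("C must be > 0")
    if len(np.unique(y)) != 2:
        raise ValueError("exactly two classes are required")
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    return LinearSVMModel(
        weights=np.asarray(clf.coef_).ravel().copy(),
        bias=float(clf.intercept_[0]),
        C=float(C),
        classes=clf.classes_.copy(),
    )


def decision_values(model: LinearSVMModel, patterns) -> np.ndarray:
    X = np.asarray(getattr(patterns, "matrix", patterns), dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError("feature count mismatch")
    return X @ model.weights + model.bias


def predict(model: LinearSVMModel, patterns) -> np.ndarray:
    """sign(w.x + b); a zero decision value maps to the positive class."""
    dec = decision_values(model, patterns)
    return np.where(dec >= 0, model.classes[1], model.classes[0])


def rank_features(model: LinearSVMModel) -> np.ndarray:
    """Feature indices by decreasing |w_j|; ties broken by ascending index."""
    return np.argsort(-np.abs(model.weights), kind="stable")


def feature_levels(
    min_voxels: int = 100, max_voxels: int = 3844, n_levels: int = 10
) -> np.ndarray:
    """Geometric progression of voxel counts from min to max.

    Ratio (max/min)^(1/(n_levels-1)), each term rounded to the nearest
    integer; the defaults give 100, 150, 225, ..., 3844.
    """
    if not (0 < min_voxels < max_voxels):
        raise ValueError("need 0 < min_voxels < max_voxels")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    k = np.arange(n_levels)
    terms = np.rint(
        min_voxels * (max_voxels / min_voxels) ** (k / (n_levels - 1))
    ).astype(int)
    if np.any(np.diff(terms) <= 0):
        raise ValueError("levels are not strictly increasing after rounding")
    return terms


@dataclass
class WeightMap:
    """Per-voxel non-negative discriminative weight |w|.

    ``feature_kind`` records whether weights came from voxel features
    (MIV) or cluster features (MIC, in which case all voxels of a cluster
    share one weight and excluded voxels carry 0).
    """

    values: np.ndarray
    feature_kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("weights must be non-negative")


def weight_map_from_voxels(model: LinearSVMModel, feature_map, n_voxels: int) -> WeightMap:
    """|w| per voxel for a voxel-feature model (unweighted voxels get 0)."""
    values = np.zeros(n_voxels)
    values[np.asarray(feature_map, dtype=int)] = np.abs(model.weights)
    return WeightMap(values, "voxel")


def weight_map_from_clusters(
    model: LinearSVMModel, part: ClusterPartition, n_voxels: int
) -> WeightMap:
    """Project cluster weights to voxels: each member inherits |w_cluster|."""
    if model.n_features != part.n_clusters:
        raise ValueError("model has one weight per cluster")
    values = np.zeros(n_voxels)
    for cid, cluster in enumerate(part.clusters):
        values[np.asarray(cluster, dtype=int)] = abs(model.weights[cid])
    return WeightMap(values, "cluster")


def select_voxels(
    weight_map: WeightMap, part: ClusterPartition | None, n_voxels: int
) -> np.ndarray:
    """Indices of the ``n_voxels`` most informative voxels (sorted).

    Voxel weights (MIV): the top-n voxels by weight, ties toward the
    lower index.  Cluster weights (MIC): whole clusters are admitted in
    decreasing weight order until the next cluster would overshoot; that
    boundary cluster is then partially admitted, in ascending voxel-index
    order, to reach exactly ``n_voxels``.
    """
    w = weight_map.values
    if part is None or weight_map.feature_kind == "voxel":
        if n_voxels > w.size:
            raise ValueError("n_voxels exceeds the number of weighted voxels")
        order = np.argsort(-w, kind="stable")
        return np.sort(order[:n_voxels])
    total = sum(len(c) for c in part.clusters)
    if n_voxels > total:
        raise ValueError("n_voxels exceeds the number of clustered voxels")
    cluster_w = np.array([w[c[0]] for c in part.clusters])
    order = np.argsort(-cluster_w, kind="stable")
    chosen: list = []
    for cid in order:
        cluster = np.sort(np.asarray(part.clusters[cid], dtype=int))
        room = n_voxels - len(chosen)
        if room == 0:
            break
        chosen.extend(cluster[:room].tolist())
    return np.sort(np.array(chosen, dtype=int))


def clusters_touching(part: ClusterPartition, voxel_set) -> np.ndarray:
    """Ids of clusters that contribute at least one voxel to ``voxel_set``."""
    sel = set(int(v) for v in np.asarray(voxel_set).ravel())
    return np.array(
        [cid for cid, c in enumerate(part.clusters) if sel.intersection(map(int, c))],
        dtype=int,
    )
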