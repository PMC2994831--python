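"""Cross-validated evaluation of the mapping pipelines.

Runs the voxel-based (MIV, and MIVs on spatially smoothed data) and
cluster-based (uMIC, mMIC, and mMICc on cubic clusters) pipelines under
run-wise k-fold cross-validation, and scores them by predictive accuracy
per feature level, ROC/AUC of the weight map against a ground-truth
informative mask (simulation only), and robustness of mapping — the mean
pairwise intersection-over-union of the voxel sets selected across folds.

Mapping is strictly training-side: per fold, the parcellation (for MIC
variants), the summarization models, the ranking SVM and the selected
voxel sets are all derived from the training runs alone; test runs are
only ever scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from . import rank as _rank
from .partition import ClusterPartition, cubic_partition, region_grow
from .preprocess import TimeSeriesDataset, extract_patterns, gaussian_smooth
from .summarize import summarize_mmic, summarize_umic
from ._utils import substream

METHODS = ("miv", "umic", "mmic", "mivs", "mmicc")


@dataclass
class FoldPlan:
    """Run-wise fold assignment for k-fold cross-validation."""

    k: int
    assignment: dict  # run id -> fold index

    def test_runs(self, fold: int):
        return [r for r, f in self.assignment.items() if f == fold]

    def train_runs(self, fold: int):
        return [r for r, f in self.assignment.items() if f != fold]


def make_folds(run_ids, k: int, seed: int = 0) -> FoldPlan:
    """Deal runs round-robin into k folds after a seeded shuffle."""
    run_ids = np.asarray(run_ids)
    _, idx = np.unique(run_ids, return_index=True)
    runs = run_ids[np.sort(idx)]
    if k < 2 or k > runs.size:
        raise ValueError(f"k must be in [2, number of runs], got {k}")
    order = substream(seed, "fold-shuffle").permutation(runs.size)
    assignment = {runs[r]: int(pos % k) for pos, r in enumerate(order)}
    return FoldPlan(k=k, assignment=assignment)


def predictive_accuracy(predicted, true) -> float:
    predicted, true = np.asarray(predicted), np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("length mismatch")
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(predicted == true))


def roc_auc(weights, truth):
    """ROC of voxel weights against a binary informative-voxel truth.

    Thresholds sweep the distinct weight values; sensitivity is the
    fraction of informative voxels at/above threshold, 1-specificity the
    same fraction among uninformative voxels.  Returns
    ((fpr, tpr), area) with the area by the trapezoidal rule over the
    full curve including (0,0) and (1,1).
    """
    w = np.asarray(getattr(weights, "values", weights), dtype=float).ravel()
    t = np.asarray(getattr(truth, "ravel", lambda: truth)(), dtype=bool).ravel()
    if w.shape != t.shape:
        raise ValueError("weights and truth mask must align")
    if t.all() or not t.any():
        raise ValueError("truth mask must contain both classes")
    fpr, tpr, _ = _roc_curve(t.astype(int), w, drop_intermediate=False)
    return (fpr, tpr), float(_auc(fpr, tpr))


def overlap_rate(set_a, set_b) -> float:
    """Intersection-over-union similarity of two voxel sets (empty/empty = 1)."""
    a = set(int(v) for v in np.asarray(list(set_a)).ravel())
    b = set(int(v) for v in np.asarray(list(set_b)).ravel())
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def robustness(selected_sets) -> float:
    """Mean pairwise intersection-over-union over >= 2 selected voxel sets."""
    sets = list(selected_sets)
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    return float(np.mean([overlap_rate(a, b) for a, b in combinations(sets, 2)]))


@dataclass
class FoldRecord:
    """Everything one (repetition, fold) produced."""

    repetition: int
    fold: int
    weight_map: _rank.WeightMap
    selected: dict  # level -> sorted voxel-index array
    accuracy: dict  # level -> test accuracy
    auc: float | None = None
    partition: ClusterPartition | None = None


@dataclass
class MappingResult:
    """Aggregated outcome of one cross-validated mapping pipeline."""

    method: str
    levels: np.ndarray
    folds: list = field(default_factory=list)
    accuracy_by_level: np.ndarray = None
    max_accuracy: float = None
    robustness_by_level: np.ndarray = None
    mean_robustness: float = None
    mean_auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "levels": [int(v) for v in self.levels],
            "accuracy_by_level": [float(a) for a in self.accuracy_by_level],
            "max_accuracy": float(self.max_accuracy),
            "robustness_by_level": [float(r) for r in self.robustness_by_level],
            "mean_robustness": float(self.mean_robustness),
            "mean_auc": None if self.mean_auc is None else float(self.mean_auc),
            "fold_accuracies": [
                {str(k): float(v) for k, v in f.accuracy.items()} for f in self.folds
            ],
        }


def _map_one_fold(method, ts, patterns, train_runs, part, size_threshold, C):
    """Training-side mapping: returns (weight map, partition or None,
    per-level classifier inputs).

    ``part`` is the shared parcellation, or None to recompute it from the
    training runs' raw series (per-fold scope).
    """
    train = patterns.subset_runs(train_runs)
    if method in ("miv", "mivs"):
        model = _rank.train_linear_svm(train, train.labels, C=C)
        wm = _rank.weight_map_from_voxels(model, train.feature_map, ts.n_voxels)
        return wm, None, train
    if method in ("umic", "mmic", "mmicc"):
        if part is None:
            part = region_grow(ts.subset_runs(train_runs), size_threshold)
        if method == "umic":
            summary = summarize_umic(patterns, part)
            train_s = summary.subset_runs(train_runs)
            test_s_full = summary
        else:
            train_s, test_s_full = summarize_mmic(train, patterns, part)
        model = _rank.train_linear_svm(train_s, train_s.labels, C=C)
        wm = _rank.weight_map_from_clusters(model, part, ts.n_voxels)
        return wm, part, (train_s, test_s_full)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def run_pipeline(
    method: str,
    ts: TimeSeriesDataset,
    design,
    *,
    size_threshold: int = 15,
    block_dims=(3, 3, 2),
    C: float = 1.0,
    levels=None,
    n_folds: int = 4,
    n_reps: int = 1,
    seed: int = 0,
    shift_volumes: int = 3,
    smoothing_fwhm_mm: float = 6.0,
    truth_mask=None,
    detrend: bool = False,
    partition_scope: str = "dataset",
) -> MappingResult:
    """Cross-validated mapping and classification with one method.

    ``method`` is one of ``miv``, ``umic``, ``mmic``, ``mivs`` (MIV on
    data smoothed at ``smoothing_fwhm_mm``) or ``mmicc`` (mMIC on cubic
    clusters of ``block_dims``).  Per fold, the summaries, the ranking
    SVM and the voxel selections are computed on training runs; at each
    feature level an SVM is retrained on the selected features and scored
    on the test runs.  If ``truth_mask`` is given, each fold's weight map
    is scored by ROC/AUC against it.

    ``partition_scope`` controls the homogeneous-cluster parcellation:
    ``"dataset"`` (default) computes it once from the full raw series —
    the parcellation is unsupervised, so this leaks no label information
    and keeps one cluster frame across folds; ``"fold"`` recomputes it
    from each fold's training runs only.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if partition_scope not in ("dataset", "fold"):
        raise ValueError("partition_scope must be 'dataset' or 'fold'")
    if method == "mivs":
        ts = gaussian_smooth(ts, smoothing_fwhm_mm)
    if detrend:
        from .preprocess import detrend_linear

        ts = detrend_linear(ts)
    patterns = extract_patterns(ts, design, shift_volumes=shift_volumes)
    if levels is None:
        levels = _rank.feature_levels()
    levels = np.asarray(levels, dtype=int)
    if levels.max() > ts.n_voxels:
        raise ValueError("largest feature level exceeds the voxel count")

    truth_flat = None
    if truth_mask is not None:
        truth_mask = np.asarray(truth_mask, dtype=bool)
        i, j, k = ts.voxel_coords.T
        truth_flat = truth_mask[i, j, k]

    shared_part = None
    if method == "mmicc":
        shared_part = cubic_partition(ts.mask_shape, ts.voxel_coords, block_dims)
    elif method in ("umic", "mmic") and partition_scope == "dataset":
        shared_part = region_grow(ts, size_threshold)

    records = []
    for rep in range(n_reps):
        plan = make_folds(ts.run_ids, n_folds, seed=substream(seed, f"rep{rep}").integers(2**31))
        for fold in range(plan.k):
            train_runs = plan.train_runs(fold)
            test_runs = plan.test_runs(fold)
            wm, part, ctx = _map_one_fold(
                method, ts, patterns, train_runs, shared_part, size_threshold, C
            )
            selected, accuracy = {}, {}
            for n in levels:
                sel = _rank.select_voxels(wm, part, int(n))
                selected[int(n)] = sel
                accuracy[int(n)] = _score_level(
                    method, patterns, ctx, part, sel, train_runs, test_runs, C
                )
            rec = FoldRecord(rep, fold, wm, selected, accuracy, partition=part)
            if truth_flat is not None:
                rec.auc = roc_auc(wm.values, truth_flat)[1]
            records.append(rec)

    return _aggregate(method, levels, records, n_reps, n_folds)


def _score_level(method, patterns, ctx, part, sel, train_runs, test_runs, C):
    """Retrain an SVM on the features selected at one level; score test runs."""
    if method in ("miv", "mivs"):
        cols = np.searchsorted(patterns.feature_map, sel)
        sub = patterns.subset_features(cols)
        train = sub.subset_runs(train_runs)
        test = sub.subset_runs(test_runs)
    else:
        train_s, test_s_full = ctx
        cids = _rank.clusters_touching(part, sel)
        train = train_s.subset_features(cids)
        test = test_s_full.subset_features(cids).subset_runs(test_runs)
    model = _rank.train_linear_svm(train, train.labels, C=C)
    return predictive_accuracy(_rank.predict(model, test), test.labels)


def _aggregate(method, levels, records, n_reps, n_folds):
    acc = np.array(
        [[rec.accuracy[int(n)] for n in levels] for rec in records]
    )  # (reps*folds, levels)
    accuracy_by_level = acc.mean(axis=0)
    rob = np.zeros((n_reps, len(levels)))
    for rep in range(n_reps):
        fold_recs = [r for r in records if r.repetition == rep]
        for li, n in enumerate(levels):
            rob[rep, li] = robustness([r.selected[int(n)] for r in fold_recs])
    robustness_by_level = rob.mean(axis=0)
    aucs = [r.auc for r in records if r.auc is not None]
    return MappingResult(
        method=method,
        levels=levels,
        folds=records,
        accuracy_by_level=accuracy_by_level,
        max_accuracy=float(accuracy_by_level.max()),
        robustness_by_level=robustness_by_level,
        mean_robustness=float(robustness_by_level.mean()),
        mean_auc=float(np.mean(aucs)) if aucs else None,
    )
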