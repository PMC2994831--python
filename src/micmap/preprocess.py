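"""Time-series containers, NIfTI I/O, detrending, smoothing and block
averaging of BOLD data into multi-voxel pattern samples.

The central containers are :class:`TimeSeriesDataset` (masked 4-D BOLD
values, one row per voxel) and :class:`PatternSet` (samples x features
response matrix with condition labels and run identifiers).  A "design"
is a :class:`pandas.DataFrame` with one row per volume and columns
``run`` (int), ``volume`` (within-run index, int) and ``condition``
(int condition code, :data:`FIXATION` = -1 for rest volumes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

from ._utils import mask_voxel_coords

#: condition code marking fixation / rest volumes in a design table
FIXATION = -1


@dataclass
class TimeSeriesDataset:
    """Masked 4-D BOLD data: ``values[v, t]`` for masked voxel v, volume t.

    Parameters
    ----------
    values : (n_voxels, n_volumes) float array
    voxel_coords : (n_voxels, 3) int array of 0-based (i, j, k) triples,
        ordered lexicographically in (k, j, i).
    voxel_dims : (3,) voxel size in mm per axis
    tr_seconds : repetition time
    run_ids : (n_volumes,) int run label per volume; runs are contiguous
    mask_shape : grid dimensions of the original volume
    """

    values: np.ndarray
    voxel_coords: np.ndarray
    voxel_dims: tuple
    tr_seconds: float
    run_ids: np.ndarray
    mask_shape: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        self.run_ids = np.asarray(self.run_ids)
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)
        self.mask_shape = tuple(int(s) for s in self.mask_shape)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (voxels x volumes)")
        if self.values.shape[0] != self.voxel_coords.shape[0]:
            raise ValueError("values and voxel_coords disagree on voxel count")
        if self.values.shape[1] != self.run_ids.shape[0]:
            raise ValueError("values and run_ids disagree on volume count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        # runs must partition the volume axis contiguously
        change = np.flatnonzero(np.diff(self.run_ids) != 0)
        seen = self.run_ids[np.r_[0, change + 1]]
        if len(set(seen.tolist())) != len(seen):
            raise ValueError("run_ids must be contiguous blocks")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    @property
    def runs(self) -> np.ndarray:
        """Unique run labels in order of appearance."""
        _, idx = np.unique(self.run_ids, return_index=True)
        return self.run_ids[np.sort(idx)]

    def run_slice(self, run) -> slice:
        idx = np.flatnonzero(self.run_ids == run)
        if idx.size == 0:
            raise KeyError(f"no such run: {run!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset_voxels(self, voxel_indices) -> "TimeSeriesDataset":
        voxel_indices = np.asarray(voxel_indices, dtype=int)
        return replace(
            self,
            values=self.values[voxel_indices].copy(),
            voxel_coords=self.voxel_coords[voxel_indices].copy(),
        )

    def subset_runs(self, runs) -> "TimeSeriesDataset":
        keep = np.isin(self.run_ids, np.asarray(list(runs)))
        return replace(
            self,
            values=self.values[:, keep].copy(),
            run_ids=self.run_ids[keep].copy(),
        )

    def to_volume(self) -> np.ndarray:
        """Embed values into the full 4-D grid (zeros outside the mask)."""
        vol = np.zeros(self.mask_shape + (self.n_volumes,), dtype=float)
        i, j, k = self.voxel_coords.T
        vol[i, j, k, :] = self.values
        return vol


@dataclass
class PatternSet:
    """Samples x features response matrix with labels and run identifiers.

    ``feature_kind`` is ``"voxel"`` (columns are voxels of a
    :class:`TimeSeriesDataset`; ``feature_map`` holds voxel indices) or
    ``"cluster"`` (columns are clusters; ``feature_map`` holds cluster ids).
    ``feature_map`` is a bijection onto the columns.
    """

    matrix: np.ndarray
    labels: np.ndarray
    sample_runs: np.ndarray
    feature_kind: str = "voxel"
    feature_map: np.ndarray = field(default=None)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        self.sample_runs = np.asarray(self.sample_runs)
        if self.feature_map is None:
            self.feature_map = np.arange(self.matrix.shape[1])
        self.feature_map = np.asarray(self.feature_map)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("labels length mismatch")
        if len(self.sample_runs) != self.matrix.shape[0]:
            raise ValueError("sample_runs length mismatch")
        if len(self.feature_map) != self.matrix.shape[1]:
            raise ValueError("feature_map must index every column")
        if len(np.unique(self.feature_map)) != len(self.feature_map):
            raise ValueError("feature_map must be a bijection")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_samples(self, idx) -> "PatternSet":
        idx = np.asarray(idx)
        return PatternSet(
            self.matrix[idx],
            self.labels[idx],
            self.sample_runs[idx],
            self.feature_kind,
            self.feature_map,
        )

    def subset_runs(self, runs) -> "PatternSet":
        return self.subset_samples(np.isin(self.sample_runs, np.asarray(list(runs))))

    def subset_features(self, cols) -> "PatternSet":
        cols = np.asarray(cols, dtype=int)
        return PatternSet(
            self.matrix[:, cols],
            self.labels,
            self.sample_runs,
            self.feature_kind,
            self.feature_map[cols],
        )


def stimulus_blocks(design: pd.DataFrame):
    """Yield (run, condition, within-run volume indices) per stimulus block.

    A block is a maximal contiguous stretch of volumes of one non-fixation
    condition within one run, in design row order.
    """
    for col in ("run", "volume", "condition"):
        if col not in design.columns:
            raise ValueError(f"design is missing column {col!r}")
    for run, sub in design.groupby("run", sort=False):
        cond = sub["condition"].to_numpy()
        vols = sub["volume"].to_numpy()
        start = 0
        for t in range(1, len(cond) + 1):
            if t == len(cond) or cond[t] != cond[start]:
                if cond[start] != FIXATION:
                    yield run, int(cond[start]), vols[start:t]
                start = t


def extract_patterns(
    ts: TimeSeriesDataset, design: pd.DataFrame, shift_volumes: int = 3
) -> PatternSet:
    """Block-average a time series into one multi-voxel sample per block.

    The series is shifted by ``shift_volumes`` volumes to account for the
    hemodynamic delay (3 volumes = 6 s at TR 2 s), then the signal is
    averaged within each stimulus block.  Shifted volumes falling past the
    end of a run are truncated (volumes are never borrowed across runs).
    """
    if shift_volumes < 0:
        raise ValueError("shift_volumes must be >= 0")
    rows, labels, sample_runs = [], [], []
    for run, condition, vols in stimulus_blocks(design):
        sl = ts.run_slice(run)
        n_run = sl.stop - sl.start
        shifted = np.asarray(vols, dtype=int) + shift_volumes
        kept = shifted[shifted < n_run]
        if kept.size < shifted.size:
            warnings.warn(
                f"run {run}: block shifted past the run end; "
                f"averaging {kept.size}/{shifted.size} volumes",
                stacklevel=2,
            )
        if kept.size == 0:
            raise ValueError(f"run {run}: shifted block has no volumes left")
        rows.append(ts.values[:, sl][:, kept].mean(axis=1))
        labels.append(condition)
        sample_runs.append(run)
    if not rows:
        raise ValueError("design contains no stimulus blocks")
    return PatternSet(
        np.array(rows),
        np.array(labels),
        np.array(sample_runs),
        feature_kind="voxel",
        feature_map=np.arange(ts.n_voxels),
    )


def detrend_linear(ts: TimeSeriesDataset) -> TimeSeriesDataset:
    """Remove, per voxel and per run, the least-squares line over volume index."""
    out = ts.values.copy()
    for run in ts.runs:
        sl = ts.run_slice(run)
        n = sl.stop - sl.start
        if n < 2:
            raise ValueError(f"run {run!r} has fewer than 2 volumes")
        t = np.arange(n, dtype=float)
        tc = t - t.mean()
        block = out[:, sl]
        slope = block @ tc / (tc @ tc)
        out[:, sl] = block - block.mean(axis=1, keepdims=True) - slope[:, None] * tc
    return replace(ts, values=out)


def gaussian_smooth(ts: TimeSeriesDataset, fwhm_mm: float) -> TimeSeriesDataset:
    """Spatially smooth each volume with a separable Gaussian kernel.

    Smoothing is mask-normalized: values*mask and the mask itself are
    convolved and divided, so no zeros leak in from outside the brain and
    spatially constant data are left unchanged.
    """
    from scipy.ndimage import gaussian_filter

    from ._utils import fwhm_to_sigma_voxels

    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be > 0")
    sigma = fwhm_to_sigma_voxels(fwhm_mm, ts.voxel_dims)
    mask = np.zeros(ts.mask_shape, dtype=float)
    i, j, k = ts.voxel_coords.T
    mask[i, j, k] = 1.0
    smooth_mask = gaussian_filter(mask, sigma=sigma, mode="constant")
    vol = ts.to_volume()
    vol = gaussian_filter(vol, sigma=tuple(sigma) + (0.0,), mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        vol /= smooth_mask[..., None]
    return replace(ts, values=vol[i, j, k, :])


def _affine(voxel_dims) -> np.ndarray:
    return np.diag(list(voxel_dims) + [1.0])


def read_bold(path, mask_path, tr_seconds=None, run_ids=None) -> TimeSeriesDataset:
    """Load a 4-D NIfTI BOLD image restricted to a binary NIfTI mask.

    ``run_ids`` assigns a run label per volume (a single run by default).
    ``tr_seconds`` overrides the TR recorded in the header.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D BOLD image, got shape {data.shape}")
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj)
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match BOLD grid {data.shape[:3]}"
        )
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask selects no voxels")
    coords = mask_voxel_coords(mask)
    zooms = img.header.get_zooms()
    if tr_seconds is None:
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if run_ids is None:
        run_ids = np.zeros(data.shape[3], dtype=int)
    i, j, k = coords.T
    return TimeSeriesDataset(
        values=data[i, j, k, :],
        voxel_coords=coords,
        voxel_dims=tuple(float(z) for z in zooms[:3]),
        tr_seconds=float(tr_seconds),
        run_ids=run_ids,
        mask_shape=data.shape[:3],
    )


def write_bold(path, ts: TimeSeriesDataset) -> None:
    """Write a dataset back to 4-D NIfTI (zeros outside the mask)."""
    img = nib.Nifti1Image(ts.to_volume(), _affine(ts.voxel_dims))
    zooms = tuple(ts.voxel_dims) + (float(ts.tr_seconds),)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def write_mask(path, mask_or_coords, grid_shape=None, voxel_dims=(1.0, 1.0, 1.0)) -> None:
    """Write a binary mask volume, from a 3-D array or a set of (i,j,k) triples."""
    arr = np.asarray(mask_or_coords)
    if arr.ndim == 3:
        mask = arr.astype(np.uint8)
    else:
        if grid_shape is None:
            raise ValueError("grid_shape is required when passing voxel coordinates")
        mask = np.zeros(grid_shape, dtype=np.uint8)
        coords = arr.reshape(-1, 3).astype(int)
        mask[coords[:, 0], coords[:, 1], coords[:, 2]] = 1
    nib.save(nib.Nifti1Image(mask, _affine(voxel_dims)), str(path))


def read_design(path) -> pd.DataFrame:
    """Read a design TSV (columns run, volume, condition; 'fixation' = rest)."""
    df = pd.read_csv(path, sep="\t", dtype={"run": int, "volume": int, "condition": str})
    cond = df["condition"].map(lambda s: FIXATION if s == "fixation" else int(s))
    return pd.DataFrame({"run": df["run"], "volume": df["volume"], "condition": cond})


def write_design(path, design: pd.DataFrame) -> None:
    out = design.copy()
    out["condition"] = [
        "fixation" if c == FIXATION else str(int(c)) for c in design["condition"]
    ]
    out.to_csv(path, sep="\t", index=False)
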