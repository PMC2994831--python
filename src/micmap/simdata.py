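"""Block-design BOLD simulator with preset informative regions and
calibrated contrast-to-noise ratio (CNR).

The simulator emulates a two-condition blocked fMRI experiment on a
32x32x5 voxel grid (3x3x4 mm voxels, TR 2 s): eight runs, each holding
three 32-s blocks per condition separated by 16-s fixation blocks.  Each
condition carries its own Gaussian white-noise spatial pattern over two
irregular connected "informative" regions; outside those regions there is
no effect at all.  Per-voxel signal time courses are the condition boxcars
convolved with a canonical double-gamma hemodynamic response, and the
whole volume is overlaid with spatiotemporal Gaussian white noise that is
spatially smoothed (4 mm FWHM by default).

CNR is defined as the spatial mean, over informative voxels, of the
temporal maximum absolute signal, divided by the temporal standard
deviation of the (post-smoothing) noise.  Because that ratio is linear in
the signal scale, the simulator rescales the signal analytically so the
measured CNR matches the requested target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import gamma as gamma_dist

from ._utils import fwhm_to_sigma_voxels, mask_voxel_coords, substream
from .preprocess import FIXATION, TimeSeriesDataset

_FACE_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


class PlacementError(RuntimeError):
    """Raised when disjoint informative regions cannot be placed."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    Defaults reproduce the reference simulation design: 32x32x5 grid of
    3x3x4 mm voxels, TR 2 s, 8 runs of three 32-s blocks per condition
    with 16-s fixations, two informative regions, noise smoothed at
    4 mm FWHM.  ``region_size_voxels`` is typically one of 15/30/60/120
    and ``cnr`` one of 0.05/0.10/0.15/0.20.
    """

    grid_shape: tuple = (32, 32, 5)
    voxel_dims: tuple = (3.0, 3.0, 4.0)
    tr_seconds: float = 2.0
    n_runs: int = 8
    blocks_per_condition_per_run: int = 3
    block_seconds: float = 32.0
    fixation_seconds: float = 16.0
    n_conditions: int = 2
    region_size_voxels: int = 60
    n_regions: int = 2
    cnr: float = 0.20
    noise_fwhm_mm: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        for name in ("block_seconds", "fixation_seconds"):
            dur = getattr(self, name)
            if dur <= 0:
                raise ValueError(f"{name} must be positive")
            ratio = dur / self.tr_seconds
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"{name} must be an integer multiple of tr_seconds")
        if self.n_conditions != 2:
            raise ValueError("the simulator supports exactly 2 conditions")
        if self.n_runs < 1 or self.blocks_per_condition_per_run < 1:
            raise ValueError("n_runs and blocks_per_condition_per_run must be >= 1")
        n_grid = int(np.prod(self.grid_shape))
        if not (1 <= self.region_size_voxels <= n_grid):
            raise ValueError("region_size_voxels must be in [1, n grid voxels]")
        if self.n_regions * self.region_size_voxels > n_grid:
            raise ValueError("requested regions do not fit in the grid")
        if self.cnr < 0:
            raise ValueError("cnr must be >= 0")

    @property
    def block_volumes(self) -> int:
        return int(round(self.block_seconds / self.tr_seconds))

    @property
    def fixation_volumes(self) -> int:
        return int(round(self.fixation_seconds / self.tr_seconds))

    @property
    def volumes_per_run(self) -> int:
        n_blocks = self.n_conditions * self.blocks_per_condition_per_run
        return n_blocks * self.block_volumes + (n_blocks + 1) * self.fixation_volumes


@dataclass
class GroundTruth:
    """Noise-free truth accompanying one simulated dataset.

    ``signal_timeseries`` holds the scaled signal for every masked voxel
    (exactly zero outside ``informative_mask``); ``condition_patterns``
    are the unscaled standard-Gaussian amplitudes per (condition,
    informative voxel); ``noise_sigma`` is the pooled temporal standard
    deviation of the post-smoothing noise field and ``signal_scale`` the
    global factor that calibrated the CNR.
    """

    informative_mask: np.ndarray
    condition_patterns: np.ndarray
    signal_timeseries: np.ndarray
    noise_sigma: float
    signal_scale: float
    informative_indices: np.ndarray = field(default=None)

    def measured_cnr(self) -> float:
        """Recompute the CNR statistic from the stored signal and noise SD."""
        peak = np.abs(self.signal_timeseries[self.informative_indices]).max(axis=1)
        return float(peak.mean() / self.noise_sigma)


def canonical_hrf(tr_seconds: float, duration_seconds: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Response gamma density with peak delay 6 s minus an undershoot gamma
    with delay 16 s weighted 1/6 (dispersions 1), scaled to unit peak.
    """
    if tr_seconds <= 0 or duration_seconds <= 0:
        raise ValueError("tr_seconds and duration_seconds must be positive")
    t = np.arange(0.0, duration_seconds, tr_seconds)
    h = gamma_dist.pdf(t, a=6.0, scale=1.0) - gamma_dist.pdf(t, a=16.0, scale=1.0) / 6.0
    peak = np.abs(h).max()
    if peak > 0:
        h = h / peak
    return h


def build_block_design(config: SimulationConfig) -> pd.DataFrame:
    """Design table for the blocked experiment (one row per volume).

    Each run alternates fixation and stimulus blocks, starting and ending
    with fixation; the order of the 2 x blocks_per_condition stimulus
    slots is a seeded random permutation per run.
    """
    rng = substream(config.seed, "block-order")
    slots = np.repeat(
        np.arange(config.n_conditions), config.blocks_per_condition_per_run
    )
    rows = []
    for run in range(config.n_runs):
        order = rng.permutation(slots)
        vol = 0

        def emit(cond, n, vol):
            for _ in range(n):
                rows.append((run, vol, cond))
                vol += 1
            return vol

        vol = emit(FIXATION, config.fixation_volumes, vol)
        for cond in order:
            vol = emit(int(cond), config.block_volumes, vol)
            vol = emit(FIXATION, config.fixation_volumes, vol)
    return pd.DataFrame(rows, columns=["run", "volume", "condition"])


def design_boxcars(design: pd.DataFrame, n_conditions: int = 2) -> np.ndarray:
    """Binary (n_volumes, n_conditions) boxcar regressors from a design table."""
    cond = design["condition"].to_numpy()
    box = np.zeros((len(design), n_conditions))
    for c in range(n_conditions):
        box[cond == c, c] = 1.0
    return box


def place_informative_regions(
    grid_shape, region_size_voxels: int, n_regions: int = 2, seed=0, max_retries: int = 100
):
    """Grow ``n_regions`` disjoint face-connected regions of exact size.

    Each region starts at a random free voxel and iteratively annexes a
    random free face-neighbor of the current region, yielding irregular
    connected shapes.  Returns (boolean mask, list of (i,j,k) coordinate
    arrays, one per region).
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "placement")
    grid_shape = tuple(int(s) for s in grid_shape)
    n_grid = int(np.prod(grid_shape))
    if n_regions * region_size_voxels > n_grid:
        raise ValueError("requested regions do not fit in the grid")
    occupied = np.zeros(grid_shape, dtype=bool)
    regions = []
    for _ in range(n_regions):
        for _attempt in range(max_retries):
            region = _grow_one_region(grid_shape, region_size_voxels, occupied, rng)
            if region is not None:
                break
        else:
            raise PlacementError(
                f"could not place {n_regions} disjoint regions of "
                f"{region_size_voxels} voxels after {max_retries} retries"
            )
        for v in region:
            occupied[v] = True
        regions.append(np.array(region))
    return occupied, regions


def _grow_one_region(grid_shape, size, occupied, rng):
    free = np.argwhere(~occupied)
    if len(free) == 0:
        return None
    start = tuple(free[rng.integers(len(free))])
    region = [start]
    in_region = {start}
    frontier = []  # free face-neighbors of the region, may hold duplicates
    _extend_frontier(start, grid_shape, occupied, in_region, frontier)
    while len(region) < size:
        frontier = [v for v in frontier if v not in in_region]
        if not frontier:
            return None  # boxed in; caller retries from a fresh start
        nxt = frontier.pop(rng.integers(len(frontier)))
        region.append(nxt)
        in_region.add(nxt)
        _extend_frontier(nxt, grid_shape, occupied, in_region, frontier)
    return region


def _extend_frontier(voxel, grid_shape, occupied, in_region, frontier):
    for off in _FACE_OFFSETS:
        nb = (voxel[0] + off[0], voxel[1] + off[1], voxel[2] + off[2])
        if all(0 <= nb[a] < grid_shape[a] for a in range(3)):
            if not occupied[nb] and nb not in in_region:
                frontier.append(nb)


def simulate_dataset(config: SimulationConfig):
    """Generate one simulated dataset.

    Returns ``(TimeSeriesDataset, GroundTruth)``.  All randomness flows
    from ``config.seed`` through independent named substreams (block
    order, region placement, condition patterns, noise).
    """
    design = build_block_design(config)
    mask = np.ones(config.grid_shape, dtype=bool)
    coords = mask_voxel_coords(mask)
    n_vox = coords.shape[0]
    n_vol = len(design)

    # informative regions and per-condition spatial patterns
    inf_mask, _regions = place_informative_regions(
        config.grid_shape,
        config.region_size_voxels,
        config.n_regions,
        seed=substream(config.seed, "placement"),
    )
    inf_flags = inf_mask[coords[:, 0], coords[:, 1], coords[:, 2]]
    inf_idx = np.flatnonzero(inf_flags)
    patterns = substream(config.seed, "pattern").standard_normal(
        (config.n_conditions, inf_idx.size)
    )

    # expected responses: per-run convolution of boxcars with the HRF
    hrf = canonical_hrf(config.tr_seconds)
    box = design_boxcars(design, config.n_conditions)
    runs = design["run"].to_numpy()
    expected = np.zeros_like(box)
    for run in range(config.n_runs):
        rows = runs == run
        for c in range(config.n_conditions):
            expected[rows, c] = np.convolve(box[rows, c], hrf)[: rows.sum()]

    # unscaled signal, nonzero only inside the informative regions
    raw_signal = patterns.T @ expected.T  # (n informative voxels, n volumes)

    # smoothed spatiotemporal Gaussian white noise
    sigma_vox = fwhm_to_sigma_voxels(config.noise_fwhm_mm, config.voxel_dims)
    noise = substream(config.seed, "noise").standard_normal(config.grid_shape + (n_vol,))
    noise = gaussian_filter(noise, sigma=tuple(sigma_vox) + (0.0,), mode="constant")
    noise = noise[coords[:, 0], coords[:, 1], coords[:, 2], :]
    noise_sigma = float(np.sqrt(noise.var(axis=1).mean()))

    # calibrate the CNR by a single global rescaling of the signal
    peak = np.abs(raw_signal).max(axis=1).mean() if inf_idx.size else 0.0
    if config.cnr > 0 and peak == 0:
        raise ValueError("cannot calibrate CNR > 0 with an empty/flat signal")
    scale = config.cnr * noise_sigma / peak if config.cnr > 0 else 0.0

    signal = np.zeros((n_vox, n_vol))
    signal[inf_idx] = scale * raw_signal
    ts = TimeSeriesDataset(
        values=signal + noise,
        voxel_coords=coords,
        voxel_dims=config.voxel_dims,
        tr_seconds=config.tr_seconds,
        run_ids=runs,
        mask_shape=config.grid_shape,
    )
    truth = GroundTruth(
        informative_mask=inf_mask,
        condition_patterns=patterns,
        signal_timeseries=signal,
        noise_sigma=noise_sigma,
        signal_scale=scale,
        informative_indices=inf_idx,
    )
    return ts, truth
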