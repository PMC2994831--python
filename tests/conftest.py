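import numpy as np
import pytest

from micmap import SimulationConfig, TimeSeriesDataset, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulation: 12x12x3 grid, 4 runs, 2 blocks/condition."""
    return SimulationConfig(
        grid_shape=(12, 12, 3),
        n_runs=4,
        blocks_per_condition_per_run=2,
        region_size_voxels=10,
        cnr=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the reference design (32x32x5, 8 runs, CNR 0.2)."""
    cfg = SimulationConfig(seed=5, cnr=0.2, region_size_voxels=60)
    ts, truth = simulate_dataset(cfg)
    return cfg, ts, truth


def make_ts(values, run_ids=None, grid=None, tr=2.0, voxel_dims=(1.0, 1.0, 1.0)):
    """Hand-built TimeSeriesDataset over a full grid of the needed size."""
    values = np.asarray(values, dtype=float)
    n_vox, n_vol = values.shape
    if grid is None:
        grid = (n_vox, 1, 1)
    assert int(np.prod(grid)) == n_vox
    mask = np.ones(grid, dtype=bool)
    from micmap._utils import mask_voxel_coords

    coords = mask_voxel_coords(mask)
    if run_ids is None:
        run_ids = np.zeros(n_vol, dtype=int)
    return TimeSeriesDataset(
        values=values,
        voxel_coords=coords,
        voxel_dims=voxel_dims,
        tr_seconds=tr,
        run_ids=np.asarray(run_ids),
        mask_shape=grid,
    )
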