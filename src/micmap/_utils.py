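"""Shared helpers: seeded substreams, FWHM conversion, voxel ordering."""

from __future__ import annotations

import hashlib

import numpy as np

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_dims_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a kernel of ``fwhm_mm``.

    Anisotropic voxels are handled per axis: sigma_mm / voxel_dim.
    """
    sigma_mm = float(fwhm_mm) / FWHM_PER_SIGMA
    return sigma_mm / np.asarray(voxel_dims_mm, dtype=float)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent named random substream derived from one master seed.

    The stream key is a stable hash of ``name`` so each component of a
    simulation (pattern, noise, placement, block order, ...) draws from
    its own reproducible stream.
    """
    key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def mask_voxel_coords(mask: np.ndarray) -> np.ndarray:
    """(i, j, k) coordinates of the True voxels of a 3-D mask.

    The order is deterministic: lexicographic in (k, j, i), i.e. the
    slice index varies slowest.  All modules rely on this ordering so
    feature indices are stable across operations.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3-D, got shape {mask.shape}")
    kji = np.argwhere(mask.transpose(2, 1, 0))
    return np.ascontiguousarray(kji[:, ::-1])


def coords_to_flat(coords: np.ndarray, grid_shape) -> np.ndarray:
    """Row-major flat index of each (i, j, k) coordinate triple."""
    coords = np.asarray(coords)
    return np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]), grid_shape)
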