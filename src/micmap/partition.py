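"""Parcellation of the masked brain into local homogeneous clusters.

The main algorithm is competitive region growing on raw time-series
correlation: every masked voxel starts as a candidate cluster; at each
iteration every pair of adjacent candidates that are mutual nearest
neighbours under the mean pairwise Pearson correlation is merged, and a
merged cluster is removed from the candidate set (finished) once its size
reaches a preset threshold Ts.  Finished cluster sizes therefore lie in
[Ts, 2(Ts-1)].  Candidates left when no mutual pair remains are excluded.

A cubic tiling baseline (:func:`cubic_partition`) ignores the signal and
cuts the grid into rectangular blocks of fixed size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TimeSeriesDataset

_FACE = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]
_EDGE_CORNER = [
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) != (0, 0, 0)
]


@dataclass
class ClusterPartition:
    """Disjoint connected voxel clusters plus the excluded remainder.

    ``clusters`` holds arrays of voxel indices (rows of the originating
    dataset's voxel axis); ``excluded`` the indices of unclustered voxels.
    """

    clusters: list
    excluded: np.ndarray
    size_threshold: int
    connectivity: str = "face"

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self, n_voxels: int) -> np.ndarray:
        """Per-voxel cluster id (0-based); -1 for excluded voxels."""
        lab = np.full(n_voxels, -1, dtype=int)
        for cid, members in enumerate(self.clusters):
            lab[members] = cid
        return lab

    def validate(self, n_voxels: int) -> None:
        all_idx = np.concatenate([np.asarray(c) for c in self.clusters] + [self.excluded])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("clusters and excluded set overlap")
        if len(all_idx) != n_voxels:
            raise ValueError("clusters + excluded do not cover all voxels")


def _offsets(connectivity: str):
    if connectivity == "face":
        return _FACE
    if connectivity in ("edge-corner", "26"):
        return _EDGE_CORNER
    raise ValueError(f"unknown connectivity {connectivity!r}")


def standardized_series(values: np.ndarray) -> np.ndarray:
    """Rows z-scored to unit norm so that dot products are Pearson r.

    A zero-variance (constant) row maps to the zero vector, making its
    correlation with anything 0 by convention.
    """
    values = np.asarray(values, dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norm > 0, centered / norm, 0.0)
    return z


def cluster_similarity(cluster_a, cluster_b, ts: TimeSeriesDataset) -> float:
    """Mean pairwise Pearson correlation between two voxel sets.

    Averages the raw time-series correlation r(v, w) over all cross pairs
    (v in A, w in B); symmetric in its arguments.  Computed exactly via
    the identity mean r = <sum_A z, sum_B z> / (#A #B) for unit-norm
    centered series z.
    """
    a = np.asarray(list(cluster_a), dtype=int)
    b = np.asarray(list(cluster_b), dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("clusters must be non-empty")
    if ts.n_volumes < 3:
        raise ValueError("need at least 3 volumes to correlate")
    z = standardized_series(ts.values[np.concatenate([a, b])])
    za, zb = z[: a.size], z[a.size :]
    return float(za.sum(axis=0) @ zb.sum(axis=0) / (a.size * b.size))


def _voxel_adjacency(coords: np.ndarray, connectivity: str):
    """List of face/edge-corner neighbour index lists per masked voxel."""
    index = {tuple(c): i for i, c in enumerate(coords)}
    offsets = _offsets(connectivity)
    nbrs = []
    for c in coords:
        lst = []
        for off in offsets:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                lst.append(j)
        nbrs.append(lst)
    return nbrs


def region_grow(
    ts: TimeSeriesDataset, size_threshold: int, connectivity: str = "face"
) -> ClusterPartition:
    """Competitive region growing into homogeneous clusters of size >= Ts.

    Deterministic: cluster ids start in voxel order (lexicographic in
    (k, j, i), the dataset ordering); argmax ties break toward the lowest
    cluster id; all mutual-nearest pairs of one sweep merge simultaneously.
    Similarities follow the raw-series mean-pairwise-correlation measure
    and are recomputed exactly after each merge.
    """
    if size_threshold < 2:
        raise ValueError("size_threshold must be >= 2")
    if ts.n_voxels == 0:
        raise ValueError("empty mask")
    z = standardized_series(ts.values)
    vox_nbrs = _voxel_adjacency(ts.voxel_coords, connectivity)

    members = {i: [i] for i in range(ts.n_voxels)}
    sums = {i: z[i].copy() for i in range(ts.n_voxels)}
    nbrs = {i: set(vox_nbrs[i]) for i in range(ts.n_voxels)}
    finished = []
    sim_cache: dict = {}
    next_id = ts.n_voxels

    def sim(a: int, b: int) -> float:
        key = (a, b) if a < b else (b, a)
        s = sim_cache.get(key)
        if s is None:
            s = float(sums[a] @ sums[b] / (len(members[a]) * len(members[b])))
            sim_cache[key] = s
        return s

    while members:
        # best neighbour per candidate: highest similarity, lowest id on ties
        best = {}
        for c, nb in nbrs.items():
            top, top_sim = -1, -np.inf
            for d in sorted(nb):
                s = sim(c, d)
                if s > top_sim:
                    top, top_sim = d, s
            if top >= 0:
                best[c] = top
        mutual = sorted(
            (c, d) for c, d in best.items() if c < d and best.get(d) == c
        )
        if not mutual:
            break
        for a, b in mutual:
            new = next_id
            next_id += 1
            members[new] = members.pop(a) + members.pop(b)
            sums[new] = sums.pop(a) + sums.pop(b)
            new_nb = (nbrs.pop(a) | nbrs.pop(b)) - {a, b}
            for d in new_nb:
                nbrs[d].discard(a)
                nbrs[d].discard(b)
                nbrs[d].add(new)
            nbrs[new] = new_nb
            if len(members[new]) >= size_threshold:
                finished.append(np.array(sorted(members.pop(new))))
                del sums[new]
                for d in nbrs.pop(new):
                    nbrs[d].discard(new)
        # drop cache entries that mention dead clusters
        sim_cache = {k: v for k, v in sim_cache.items() if k[0] in members and k[1] in members}

    excluded = np.array(sorted(v for m in members.values() for v in m), dtype=int)
    finished.sort(key=lambda c: int(c[0]))
    return ClusterPartition(finished, excluded, size_threshold, connectivity)


def cubic_partition(
    mask_shape, voxel_coords: np.ndarray, block_dims
) -> ClusterPartition:
    """Tile the grid with rectangular blocks of ``block_dims`` voxels.

    Each cluster is the set of masked voxels inside one block; clusters
    holding half the nominal block volume or less are excluded.
    """
    block_dims = tuple(int(b) for b in block_dims)
    if any(b < 1 for b in block_dims):
        raise ValueError("block_dims must be positive")
    coords = np.asarray(voxel_coords, dtype=int)
    block_of = tuple(coords[:, a] // block_dims[a] for a in range(3))
    keys = np.stack(block_of, axis=1)
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
    nominal = int(np.prod(block_dims))
    clusters, excluded = [], []
    start = 0
    sorted_keys = keys[order]
    for t in range(1, len(order) + 1):
        if t == len(order) or (sorted_keys[t] != sorted_keys[start]).any():
            block = np.sort(order[start:t])
            if block.size > nominal / 2:
                clusters.append(block)
            else:
                excluded.extend(block.tolist())
            start = t
    clusters.sort(key=lambda c: int(c[0]))
    return ClusterPartition(
        clusters, np.array(sorted(excluded), dtype=int), nominal, "face"
    )
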