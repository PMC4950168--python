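"""Recursive landscape decomposition into clusters.

Clusters are defined purely by the shape of the activation landscape:
starting from the highest in-mask local maximum, a cluster grows
outward (never doubling back toward the peak) and stops along each path
where the downhill slope turns upward — the signature of leaving one
hill's flank for the next. Claimed voxels are removed and the procedure
repeats from the next-highest remaining local maximum until no local
maxima remain. No cluster-forming threshold is involved (an optional
liberal pre-threshold exists purely to shrink the search region).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _core
from .stats import StatLandscape

__all__ = [
    "ClusteringConfig",
    "Cluster",
    "ClusterSet",
    "find_local_maxima",
    "grow_cluster",
    "decompose",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """Knobs of the cluster definition, shared across the whole pipeline.

    Attributes
    ----------
    connectivity : {6, 18, 26}
        Voxel neighborhood used for maxima, growth, edges and adjacency.
    pre_threshold : float or None
        Optional liberal p-value threshold (e.g. 0.05); voxels with
        landscape value below ``-log10(pre_threshold)`` are excluded
        from decomposition. ``None`` (default) is fully threshold-free.
    normalize_slope : bool
        Divide each step's slope by its physical step length (mm). Off
        by default: the slope is the raw value difference per step.
    tie_epsilon : float
        Treat value differences smaller than this as ties when testing
        local maximality (guards against flat plateaus in quantized
        maps). 0 keeps the strict definition.
    """

    connectivity: int = 26
    pre_threshold: float | None = None
    normalize_slope: bool = False
    tie_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.pre_threshold is not None and not (0.0 < self.pre_threshold < 1.0):
            raise ValueError("pre_threshold must be a p-value in (0, 1)")

    def offsets(self, voxel_size: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        offs = _core.neighborhood_offsets(self.connectivity)
        off_len = np.sqrt(((offs * np.asarray(voxel_size, float)) ** 2).sum(axis=1))
        return offs, off_len


@dataclass
class Cluster:
    """One cluster of the decomposition.

    ``voxels`` is an (n, 3) integer array of 0-based voxel coordinates;
    ``score`` is the cluster activation score, the sum of landscape
    values over the cluster (so both extent and height count).
    """

    voxels: np.ndarray
    peak: tuple[int, int, int]
    peak_value: float
    score: float
    _parent: "ClusterSet | None" = field(default=None, repr=False, compare=False)
    _label: int = field(default=0, repr=False, compare=False)

    @property
    def size(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def edge_voxels(self) -> np.ndarray:
        """Voxels of this cluster with >= 1 in-mask neighbor outside it."""
        if self._parent is None:
            raise ValueError("cluster is detached from its ClusterSet")
        return self._parent.edge_voxels(self._label)


class ClusterSet:
    """A complete, disjoint labeling of the in-mask landscape.

    Stores the integer label grid (0 = unassigned or out of mask) plus
    per-cluster peak/score arrays; ``Cluster`` views are materialized on
    demand. Cluster labels run 1..n_clusters in order of decreasing
    seeding-peak value (the order in which the decomposition found
    them); after combination, surviving clusters are renumbered in the
    same order.
    """

    def __init__(
        self,
        label_grid: np.ndarray,
        landscape: StatLandscape,
        config: ClusteringConfig,
        peak_lin: np.ndarray,
    ) -> None:
        self.label_grid = np.asarray(label_grid, dtype=np.int32)
        self.landscape = landscape
        self.config = config
        self.peak_lin = np.asarray(peak_lin, dtype=np.int64)
        self.n_clusters = int(self.peak_lin.shape[0])
        flat = self.label_grid.ravel()
        counts = np.bincount(flat, minlength=self.n_clusters + 1)
        self.sizes = counts[1 : self.n_clusters + 1].astype(np.int64)
        sums = np.bincount(flat, weights=landscape.values.ravel(), minlength=self.n_clusters + 1)
        self.scores = sums[1 : self.n_clusters + 1]
        self.peak_values = landscape.values.ravel()[self.peak_lin] if self.n_clusters else np.empty(0)

    def __len__(self) -> int:
        return self.n_clusters

    def peak_coords(self, label: int) -> tuple[int, int, int]:
        lin = int(self.peak_lin[label - 1])
        ny, nz = self.label_grid.shape[1:]
        return (lin // (ny * nz), (lin // nz) % ny, lin % nz)

    def cluster_voxels(self, label: int) -> np.ndarray:
        return np.argwhere(self.label_grid == label)

    def edge_voxels(self, label: int) -> np.ndarray:
        """Edge voxels of one cluster: members with an in-mask neighbor
        outside the cluster (other clusters or unassigned ground)."""
        offs = _core.neighborhood_offsets(self.config.connectivity)
        vox = self.cluster_voxels(label)
        mask = self.landscape.mask
        shape = self.label_grid.shape
        is_edge = np.zeros(vox.shape[0], dtype=bool)
        for off in offs:
            nb = vox + off
            ok = np.all((nb >= 0) & (nb < shape), axis=1)
            idx = tuple(nb[ok].T)
            outside = mask[idx] & (self.label_grid[idx] != label)
            is_edge[np.flatnonzero(ok)[outside]] = True
        return vox[is_edge]

    @property
    def clusters(self) -> list[Cluster]:
        out = []
        for k in range(1, self.n_clusters + 1):
            c = Cluster(
                voxels=self.cluster_voxels(k),
                peak=self.peak_coords(k),
                peak_value=float(self.peak_values[k - 1]),
                score=float(self.scores[k - 1]),
                _parent=self,
                _label=k,
            )
            out.append(c)
        return out

    def max_score(self) -> float:
        return float(self.scores.max()) if self.n_clusters else 0.0


def _availability(landscape: StatLandscape, config: ClusteringConfig) -> np.ndarray:
    avail = landscape.mask.copy()
    if config.pre_threshold is not None:
        avail &= landscape.values > -np.log10(config.pre_threshold)
    return avail


def find_local_maxima(
    landscape: StatLandscape,
    available: np.ndarray | None = None,
    config: ClusteringConfig = ClusteringConfig(),
) -> np.ndarray:
    """Local maxima of the available region, sorted by descending value
    (ties by ascending linear index).

    A local maximum is a voxel whose value strictly exceeds every
    available in-mask neighbor; isolated voxels qualify vacuously,
    plateaus never do.
    """
    if available is None:
        available = _availability(landscape, config)
    else:
        available = np.asarray(available, dtype=bool) & landscape.mask
    offs, _ = config.offsets(landscape.voxel_size)
    lins = _core.local_maxima_kernel(
        landscape.values, available.astype(np.uint8), offs, float(config.tie_epsilon)
    )
    vals = landscape.values.ravel()[lins]
    order = np.lexsort((lins, -vals))
    lins = lins[order]
    ny, nz = landscape.shape[1:]
    return np.column_stack((lins // (ny * nz), (lins // nz) % ny, lins % nz))


def grow_cluster(
    landscape: StatLandscape,
    peak: tuple[int, int, int],
    available: np.ndarray | None = None,
    config: ClusteringConfig = ClusteringConfig(),
) -> Cluster:
    """Grow a single cluster from ``peak`` over the available region.

    ``peak`` must be an available strict local maximum. Growth is a
    breadth-first frontier expansion ordered by (distance from peak,
    linear index); each step must move strictly farther from the peak,
    and stops where the slope from the accepting parent is strictly
    more positive than the slope into that parent.
    """
    if available is None:
        available = _availability(landscape, config)
    else:
        available = np.asarray(available, dtype=bool) & landscape.mask
    px, py, pz = (int(c) for c in peak)
    if not available[px, py, pz]:
        raise ValueError(f"peak {peak} is not available")
    offs, off_len = config.offsets(landscape.voxel_size)
    if not _is_peak(landscape, available, offs, (px, py, pz), config.tie_epsilon):
        raise ValueError(f"peak {peak} is not a local maximum of the available region")
    shape = landscape.shape
    V = int(np.prod(shape))
    labels = np.where(available, np.int32(0), np.int32(-1))
    stamp = np.zeros(V, np.int64)
    scratch = [np.empty(V, np.float64) for _ in range(3)]
    hd = np.empty(V + 1, np.float64)
    hl = np.empty(V + 1, np.int64)
    members = np.empty(V, np.int64)
    n = _core.grow_kernel(
        landscape.values,
        labels,
        landscape.mask,
        offs,
        off_len,
        landscape.voxel_size,
        1,
        px,
        py,
        pz,
        stamp,
        scratch[0],
        scratch[1],
        scratch[2],
        hd,
        hl,
        members,
        config.normalize_slope,
    )
    lins = np.sort(members[:n])
    ny, nz = shape[1:]
    vox = np.column_stack((lins // (ny * nz), (lins // nz) % ny, lins % nz))
    vals = landscape.values.ravel()[lins]
    return Cluster(
        voxels=vox,
        peak=(px, py, pz),
        peak_value=float(landscape.values[px, py, pz]),
        score=float(vals.sum()),
    )


def _is_peak(landscape, available, offs, peak, eps) -> bool:
    x, y, z = peak
    v = landscape.values[x, y, z]
    shape = landscape.shape
    for dx, dy, dz in offs:
        xx, yy, zz = x + dx, y + dy, z + dz
        if 0 <= xx < shape[0] and 0 <= yy < shape[1] and 0 <= zz < shape[2]:
            if available[xx, yy, zz] and landscape.values[xx, yy, zz] >= v - eps:
                return False
    return True


def decompose(
    landscape: StatLandscape,
    config: ClusteringConfig = ClusteringConfig(),
) -> ClusterSet:
    """Decompose the landscape into clusters, highest peak first.

    Repeatedly grows a cluster from the highest remaining available
    local maximum and removes its voxels, until no local maxima remain.
    Voxels never claimed by any cluster keep label 0. With
    ``config.pre_threshold`` set, sub-threshold voxels are excluded from
    availability beforehand (a speed device; results are identical when
    the threshold lies below every in-mask value).
    """
    avail = _availability(landscape, config)
    offs, off_len = config.offsets(landscape.voxel_size)
    labels, peak_lin = _core.decompose_kernel(
        landscape.values,
        avail,
        offs,
        off_len,
        landscape.voxel_size,
        float(config.tie_epsilon),
        config.normalize_slope,
    )
    return ClusterSet(labels, landscape, config, peak_lin)
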