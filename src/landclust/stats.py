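"""Group-level statistics and the activation landscape.

The analysis operates on an *activation landscape*: a 3D grid of
``-log10(p)`` values derived from a voxel-wise statistical map. For a
one-sample design (per-subject contrast maps) the map is the one-sample
t statistic across subjects, converted voxel-wise to a p-value and then
to ``-log10(p)``. Height in the landscape therefore measures evidence
against the null at each voxel; cluster definitions downstream depend
only on the *shape* of this landscape, never on a cluster-forming
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "SubjectStack",
    "StatLandscape",
    "group_tmap",
    "tmap_to_landscape",
    "LOG_BASE",
]

#: Base of the logarithm used for landscape values. Cluster membership is
#: invariant to this choice (the transform is monotone in |t|); cluster
#: activation scores are not, so it is fixed once, package-wide.
LOG_BASE = 10.0

#: Lower clip for p-values so that -log10(p) stays finite.
DEFAULT_P_FLOOR = 1e-300


@dataclass
class SubjectStack:
    """A stack of per-subject 3D contrast maps sharing one grid and mask.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, nx, ny, nz)
        Per-subject contrast values (arbitrary contrast units).
    mask : ndarray of bool, shape (nx, ny, nz)
        Analysis mask; out-of-mask voxels are ignored everywhere.
    voxel_size : ndarray, shape (3,)
        Physical voxel edge lengths in mm.
    affine : ndarray, shape (4, 4), optional
        Voxel-to-mm affine carried through to any volumes written out.
    """

    data: np.ndarray
    mask: np.ndarray
    voxel_size: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (subject, x, y, z); got shape {self.data.shape}")
        if self.data.shape[1:] != self.mask.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match volume shape {self.data.shape[1:]}"
            )
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects for a one-sample t-test")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class StatLandscape:
    """A 3D activation landscape of ``-log10(p)`` values with a mask.

    Values are finite and >= 0 at every in-mask voxel; out-of-mask voxels
    are never compared or visited by the clustering machinery.
    """

    values: np.ndarray
    mask: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)
        if self.values.ndim != 3:
            raise ValueError("landscape values must be a 3D grid")
        if self.values.shape != self.mask.shape:
            raise ValueError("mask shape does not match values shape")
        inside = self.values[self.mask]
        if inside.size and not np.isfinite(inside).all():
            raise ValueError("landscape contains non-finite values inside the mask")
        if inside.size and (inside < 0).any():
            raise ValueError("landscape values must be >= 0 inside the mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def group_tmap(stack: SubjectStack) -> tuple[np.ndarray, int, np.ndarray]:
    """One-sample t statistic across subjects at every voxel.

    Returns ``(t, df, degenerate)`` where ``t = mean / (sd / sqrt(n))``
    with ``sd`` the ddof-1 sample standard deviation, ``df = n - 1``, and
    ``degenerate`` flags voxels whose across-subject variance is zero.
    Those voxels carry no evidence and get ``t = 0`` (rather than +/-inf)
    so they can never seed a cluster.
    """
    n = stack.n_subjects
    mean = stack.data.mean(axis=0)
    sd = stack.data.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[degenerate] = 0.0
    return t, n - 1, degenerate


def tmap_to_landscape(
    t: np.ndarray,
    df: int,
    mask: np.ndarray,
    *,
    voxel_size: np.ndarray | tuple[float, float, float] = (1.0, 1.0, 1.0),
    two_sided: bool = True,
    p_floor: float = DEFAULT_P_FLOOR,
    affine: np.ndarray | None = None,
) -> StatLandscape:
    """Convert a t-map to a ``-log10(p)`` activation landscape.

    Two-sided p-values by default, since contrast maps can be negative;
    with ``two_sided=False`` only positive t counts as evidence. The
    transform is strictly monotone in |t| at fixed df, so voxel ranking
    (and hence peak order downstream) is the same on |t| and on the
    landscape. p is clipped below at ``p_floor`` to keep values finite.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not np.isfinite(t[mask]).all():
        raise ValueError("non-finite t values inside the mask")
    # stdtr(df, x) is the t CDF; sf(|t|) = stdtr(df, -|t|)
    sf = special.stdtr(df, -np.abs(t))
    if two_sided:
        p = 2.0 * sf
    else:
        p = special.stdtr(df, -t)
    p = np.clip(p, p_floor, 1.0)
    values = -np.log10(p)
    values[~mask] = 0.0
    return StatLandscape(
        values=values, mask=mask, voxel_size=np.asarray(voxel_size, dtype=float), affine=affine
    )
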