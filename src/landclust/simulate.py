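"""Simulated multi-subject contrast stacks with a planted effect region.

The validation design: each simulated subject's contrast map is
spatially smoothed Gaussian noise (FWHM in mm), standardized to unit
voxel-wise SD, plus a constant effect added inside a contiguous
"true effect" region. The effect size is therefore contrast / noise-SD
by construction. The default region is a ~220-voxel ellipsoid — the
scale of a human amygdala at 2 mm isotropic voxels — centered in a
48x48x48 grid, standing in for an atlas-defined anatomical region so
that no atlas files are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .stats import SubjectStack

__all__ = [
    "SimulationScenario",
    "make_region",
    "smooth_gaussian",
    "simulate_stack",
    "fwhm_to_sigma",
]

#: FWHM of a Gaussian = sigma * 2*sqrt(2 ln 2)
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Default ellipsoid semi-axes in voxels: 221 voxels on the default grid,
#: comparable to an amygdala at 2 mm voxels.
DEFAULT_RADII = (4.0, 3.8, 3.4)


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / _FWHM_FACTOR


def make_region(
    grid_shape: tuple[int, int, int],
    center: tuple[int, int, int] | None = None,
    radii: tuple[float, float, float] = DEFAULT_RADII,
) -> np.ndarray:
    """Boolean ellipsoidal region: voxels with sum((d_i/r_i)^2) <= 1.

    ``radii`` are semi-axes in voxel units; ``radii=(0,0,0)`` gives the
    single center voxel. The ellipsoid must fit inside the grid and be
    non-empty.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if center is None:
        center = tuple(s // 2 for s in grid_shape)
    for c, r, s in zip(center, radii, grid_shape):
        if r < 0:
            raise ValueError("radii must be >= 0")
        if c - r < 0 or c + r > s - 1:
            raise ValueError("ellipsoid does not fit in the grid")
    idx = np.indices(grid_shape, dtype=np.float64)
    q = np.zeros(grid_shape)
    for ax in range(3):
        d = idx[ax] - center[ax]
        if radii[ax] == 0:
            q += np.where(d == 0, 0.0, np.inf)
        else:
            q += (d / radii[ax]) ** 2
    region = q <= 1.0
    if not region.any():
        raise ValueError("region is empty")
    return region


def smooth_gaussian(
    volume: np.ndarray,
    fwhm: float,
    voxel_size: tuple[float, float, float] | np.ndarray = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Gaussian smoothing with FWHM given in mm (0 = identity).

    sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` converted to voxel
    units via the voxel size.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return np.asarray(volume, dtype=np.float64).copy()
    sigma = [fwhm_to_sigma(fwhm) / v for v in np.asarray(voxel_size, dtype=np.float64)]
    return gaussian_filter(np.asarray(volume, dtype=np.float64), sigma)


@dataclass
class SimulationScenario:
    """Parameters of one synthetic experiment.

    Defaults reproduce the reference validation design: 32 subjects,
    effect size 0.8 (contrast / noise SD), 4 mm FWHM smoothed noise on a
    48^3 grid of 2 mm voxels, with a ~220-voxel ellipsoidal effect
    region. ``rescale_noise`` standardizes each subject's smoothed noise
    volume to mean 0, SD 1 so the nominal effect size is exact by
    construction (smoothing alone would shrink the noise SD).
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    region: np.ndarray | None = None
    n_subjects: int = 32
    effect_size: float = 0.8
    fwhm: float = 4.0
    seed: int | np.random.SeedSequence | None = 0
    rescale_noise: bool = True
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.region is None:
            self.region = make_region(self.grid_shape)
        self.region = np.asarray(self.region, dtype=bool)
        if self.region.shape != tuple(self.grid_shape):
            raise ValueError("region shape does not match grid_shape")
        if not self.region.any():
            raise ValueError("region is empty")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.fwhm < 0:
            raise ValueError("fwhm must be >= 0")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != tuple(self.grid_shape):
                raise ValueError("mask shape does not match grid_shape")


def simulate_stack(
    scenario: SimulationScenario,
    seed: int | np.random.SeedSequence | None = None,
) -> SubjectStack:
    """Generate one multi-subject stack under the scenario.

    Per subject: draw i.i.d. standard-normal voxel noise, smooth it at
    the scenario FWHM, standardize the volume (if ``rescale_noise``),
    then add ``effect_size`` at every voxel of the (sharp-edged) effect
    region — the noise is smoothed, the effect is not. ``seed``
    overrides the scenario's own seed when given.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    shape = tuple(scenario.grid_shape)
    data = np.empty((scenario.n_subjects, *shape))
    for s in range(scenario.n_subjects):
        w = rng.standard_normal(shape)
        w = smooth_gaussian(w, scenario.fwhm, scenario.voxel_size)
        if scenario.rescale_noise:
            w = (w - w.mean()) / w.std()
        if scenario.effect_size != 0:
            w[scenario.region] += scenario.effect_size
        data[s] = w
    mask = scenario.mask if scenario.mask is not None else np.ones(shape, dtype=bool)
    return SubjectStack(data, mask, np.asarray(scenario.voxel_size, dtype=np.float64))
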