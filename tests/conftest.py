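import numpy as np
import pytest

from landclust import StatLandscape


def make_landscape(values, mask=None, voxel_size=(1.0, 1.0, 1.0)) -> StatLandscape:
    """Wrap a raw array (1D/2D/3D) as a StatLandscape for tests."""
    values = np.asarray(values, dtype=np.float64)
    while values.ndim < 3:
        values = values[..., None]
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        while mask.ndim < 3:
            mask = mask[..., None]
    return StatLandscape(values=values, mask=mask, voxel_size=np.asarray(voxel_size, float))


def random_landscape(rng, shape=(6, 6, 3), smooth=1.0) -> StatLandscape:
    """A small random non-negative landscape with mild spatial structure."""
    from scipy.ndimage import gaussian_filter

    vals = rng.standard_normal(shape)
    if smooth:
        vals = gaussian_filter(vals, smooth)
    vals = vals - vals.min()  # non-negative
    return make_landscape(vals)


@pytest.fixture
def rng():
    return np.random.default_rng(20160707)
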