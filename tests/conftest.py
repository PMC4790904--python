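import numpy as np
import pytest

from roisummary import ROIMask, ScalarMap, SubjectFirstLevel, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid6():
    return VolumeGrid((6, 6, 6))


def make_random_flm(grid, rng, with_series=True, n_timepoints=24, df=38, t_loc=0.5):
    """A subject with random beta/t maps (and an unrelated random series)."""
    beta = rng.normal(size=grid.shape)
    t = rng.normal(loc=t_loc, scale=1.5, size=grid.shape)
    series = (
        rng.normal(size=grid.shape + (n_timepoints,)) if with_series else None
    )
    return SubjectFirstLevel(
        beta=ScalarMap(grid, beta),
        tmap=ScalarMap(grid, t),
        df=df,
        series=series,
    )


def make_random_roi(grid, rng, max_voxels=100):
    """A random nonempty voxel subset of at most ``max_voxels`` voxels."""
    n_total = grid.n_voxels
    n = int(rng.integers(1, min(max_voxels, n_total) + 1))
    flat = rng.choice(n_total, size=n, replace=False)
    data = np.zeros(n_total, dtype=bool)
    data[flat] = True
    return ROIMask(grid, data.reshape(grid.shape))


@pytest.fixture
def random_flm(grid6, rng):
    return make_random_flm(grid6, rng)
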