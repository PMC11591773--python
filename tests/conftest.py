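import numpy as np
import pytest

from lastfit import synthetic
from lastfit.grid import SurfaceGrid


@pytest.fixture(scope="session")
def footprint():
    return synthetic.make_footprint(synthetic.SurfaceSpec(seed=7))


@pytest.fixture(scope="session")
def last_and_footprint(footprint):
    last, gap = synthetic.make_last_from_footprint(footprint, seed=7)
    return last, footprint, gap


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def uniform_block():
    """A 6x6 block on a uniform lattice with its (u, v) node parameters."""
    u6 = np.arange(6) / 5.0
    return u6, u6.copy()


def make_affine_grid(nx=11, ny=11, a=27.0, bx=0.01, by=-0.02):
    x = np.linspace(0.0, 100.0, nx)
    y = np.linspace(0.0, 80.0, ny)
    z = a + bx * x[:, None] + by * y[None, :]
    return SurfaceGrid(z, x, y)


@pytest.fixture()
def affine_grid():
    return make_affine_grid()
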