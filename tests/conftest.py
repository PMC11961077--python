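import numpy as np
import pytest

from cglo.core import SliceStack
from cglo.geometry import make_parallel_geometry
from cglo.phantoms import PhantomSpec, generate_phantom_stack


@pytest.fixture(scope="session")
def small_geometry():
    return make_parallel_geometry(12, 5)


@pytest.fixture(scope="session")
def phantom_stack_32() -> SliceStack:
    return generate_phantom_stack(PhantomSpec(side=32, n_slices=6, seed=7))


@pytest.fixture(scope="session")
def disk_64():
    """Centered uniform disk of radius 20 in a 64x64 image."""
    yy, xx = np.mgrid[0:64, 0:64]
    c = 63 / 2
    return (((xx - c) ** 2 + (yy - c) ** 2) <= 20 ** 2).astype(float)


def dense_operator(geom):
    """Independent dense materialization of the forward operator, built
    column by column from unit-pixel images."""
    from cglo.geometry import radon_forward

    side = geom.side
    cols = []
    for j in range(side * side):
        e = np.zeros(side * side)
        e[j] = 1.0
        cols.append(radon_forward(e.reshape(side, side), geom).values.ravel())
    return np.stack(cols, axis=1)
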