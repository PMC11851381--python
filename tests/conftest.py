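import numpy as np
import pytest

from craniorec.phantom import PhantomSpec, make_skull_phantom
from craniorec.volio import BinaryVolume


@pytest.fixture(scope="session")
def desk_spec():
    """Desk-scale phantom spec: 64x64x32 at 2 mm (128x128x64 mm extent)."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom64(desk_spec):
    return make_skull_phantom(desk_spec)


@pytest.fixture(scope="session")
def small_spec():
    """Coarse training-scale spec: 32x32x16 at 4 mm (same physical extent)."""
    return PhantomSpec(dims=(32, 32, 16), spacing=(4.0, 4.0, 4.0), thickness=6.0)


@pytest.fixture(scope="session")
def phantom32(small_spec):
    return make_skull_phantom(small_spec)


@pytest.fixture()
def unit_grid():
    """Empty 11^3 unit-spacing grid for shape-mask lattice tests."""
    return BinaryVolume(np.zeros((11, 11, 11), dtype=np.uint8), spacing=(1, 1, 1))


def random_mask(rng, shape):
    return (rng.random(shape) > 0.5).astype(np.uint8)
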