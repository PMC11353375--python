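import numpy as np
import pytest
from hypothesis import settings

from cdmifuse.grid import GridSpec
from cdmifuse.phantoms import TumorPhantomSpec, build_tumor_phantom

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid():
    """Isotropic 32^3 grid at 2 mm, centred on the origin."""
    return GridSpec.centered((32, 32, 32), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def tumor_scene():
    """A small concentric-sphere phantom used across tests."""
    grid = GridSpec.centered((48, 48, 48), (1.5, 1.5, 1.5))
    return build_tumor_phantom(TumorPhantomSpec(), grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
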