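import numpy as np
import pytest

from scdiff.phantom import (
    ProjectionGeometry,
    lung_phantom_spec,
    make_phantom,
)
from scdiff.schedule import build_linear_schedule


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def schedule_1000_250():
    return build_linear_schedule(1000, 1e-4, 0.02, k=250)


@pytest.fixture(scope="session")
def fixture_phantom_128():
    """Reference thorax phantom at the resolution used for FBP checks."""
    return make_phantom(lung_phantom_spec(jitter=False), 128)


@pytest.fixture(scope="session")
def fixture_phantom_64():
    return make_phantom(lung_phantom_spec(jitter=False), 64)


@pytest.fixture(scope="session")
def full_view_geometry():
    return ProjectionGeometry(n_angles=360)
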