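import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from primescatter import build_hex_device
from primescatter.reference import FIELD_EXTENT, GRID_RADIUS, STUDY_BEAMS

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_device():
    """The 247-block test modulator at the middle diameter."""
    return build_hex_device(*FIELD_EXTENT, r=GRID_RADIUS, d_nom=0.273)


@pytest.fixture(scope="session")
def beams():
    return STUDY_BEAMS


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
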