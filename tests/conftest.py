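import numpy as np
import pytest

from ramanline import (
    ChannelGeometry,
    MeasurementParams,
    Rig,
    TimingConfig,
    default_library,
    default_profile,
)


@pytest.fixture
def profile():
    return default_profile()


@pytest.fixture
def quiet_profile():
    """Noise-free instrument for deterministic assertions."""
    return default_profile().model_copy(update={"noise_sd": 0.0})


@pytest.fixture
def library():
    return default_library()


@pytest.fixture
def geometry():
    return ChannelGeometry()


@pytest.fixture
def timing():
    return TimingConfig()


@pytest.fixture
def params():
    return MeasurementParams()


@pytest.fixture
def rig(geometry):
    return Rig(geometry, rng=0)


@pytest.fixture
def quiet_rig(geometry, quiet_profile):
    return Rig(geometry, profile=quiet_profile, rng=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
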