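import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def acq():
    from phosphoshift.simulate import AcquisitionSpec

    return AcquisitionSpec()


@pytest.fixture
def constants():
    from phosphoshift.chemistry import ShiftConstants

    return ShiftConstants()
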