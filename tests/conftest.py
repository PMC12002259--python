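import numpy as np
import pytest

from ringpool import (
    AssemblyParams,
    RAD52_FITTED,
    DEFAULT_CALIBRATION,
)


@pytest.fixture(scope="session")
def fitted_params() -> AssemblyParams:
    """The published global-fit parameters for the full-length protein."""
    return RAD52_FITTED


@pytest.fixture(scope="session")
def calib():
    return DEFAULT_CALIBRATION


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
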