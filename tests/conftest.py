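import numpy as np
import pytest

from manucount import (
    HandCountParams,
    NoiseModel,
    calibrate,
    compute_differential,
    rest_log,
)
from manucount.hand_algorithm import CalibrationResult


@pytest.fixture(scope="session")
def default_params():
    return HandCountParams()


@pytest.fixture(scope="session")
def fixed_calibration():
    """A frozen, typical calibration (sigma ~ 1.2 -> runs of 6 / 8)."""
    return CalibrationResult(
        sigma=1.2, n_two_axes=6, n_one_axis=8, threshold=8.0, lp_cutoff=8.0
    )


@pytest.fixture(scope="session")
def device_calibration(default_params):
    """Calibration measured on a simulated 300 s rest recording."""
    diff = compute_differential(rest_log(300.0, noise=NoiseModel(seed=1)))
    return calibrate(diff, default_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
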