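import numpy as np
import pytest

from vsmcal import calibrate, default_parameters, reference_run


@pytest.fixture(scope="session")
def calibrated():
    """(params, CalibrationResult) for the default study conditions."""
    return calibrate(default_parameters())


@pytest.fixture(scope="session")
def params(calibrated):
    return calibrated[0]


@pytest.fixture(scope="session")
def baseline(calibrated):
    return calibrated[1].baseline_state


@pytest.fixture(scope="session")
def calres(calibrated):
    return calibrated[1]


@pytest.fixture(scope="session")
def ref_run(params, baseline):
    """The 30-minute elevated-matrix-calcium reference trajectory."""
    return reference_run(params, baseline)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
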