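import numpy as np
import pytest

import raschkit as rk


@pytest.fixture(scope="session")
def study_data():
    """One seeded study matrix: 300 simulees + the perfect responder."""
    cfg = rk.SimulationConfig(seed=7, append_perfect_responder=True)
    return rk.build_study_dataset(cfg)


@pytest.fixture(scope="session")
def calibrated(study_data):
    """Calibration of the study matrix with fit columns filled in."""
    result = rk.jmle_calibrate(study_data)
    rk.add_fit_statistics(study_data, result)
    return result


@pytest.fixture(scope="session")
def difficulties():
    return np.asarray(rk.STUDY_DIFFICULTIES)
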