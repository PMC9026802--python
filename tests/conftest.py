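import numpy as np
import pytest

from pmtperf import AcquisitionParams, ArterialInputFunction
from pmtperf.aif import AifParams


@pytest.fixture
def acq():
    return AcquisitionParams()


@pytest.fixture
def protocol_times(acq):
    return acq.frame_times()


@pytest.fixture
def gamma_aif(protocol_times):
    """Parametric bolus+washout plasma curve on the protocol frame grid."""
    return ArterialInputFunction.parametric(protocol_times, AifParams())


@pytest.fixture
def rng():
    return np.random.default_rng(20240889)


@pytest.fixture
def feature_row():
    """A complete 10-predictor row (printed-scale units)."""
    return {
        "age_yr": 50.0, "ktrans": 0.4, "kep": 1.5, "vp": 0.02, "ve": 0.3,
        "ttp_s": 110.0, "cmax": 25.0, "volume_mm3": 2.0e4,
        "surface_mm2": 1.2e4, "maxdiam_mm": 55.0,
    }
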