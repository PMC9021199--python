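import numpy as np
import pytest

from shellseasons import synthetic as syn
from shellseasons.chronology import CalibrationCurve


@pytest.fixture(scope="session")
def wiggly_curve():
    """A realistic synthetic calibration curve (monotone mean + wiggles)."""
    return syn.simulate_calcurve(seed=1)


@pytest.fixture(scope="session")
def identity_curve():
    """Curve with 14C age equal to calendar age and near-zero curve error."""
    cal = np.arange(6000.0, 11000.0, 5.0)
    return CalibrationCurve(name="identity", cal_bp=cal, c14_age=cal.copy(),
                            sigma=np.full_like(cal, 0.01))


@pytest.fixture(scope="session")
def climate_scenario():
    return syn.default_climate_scenario()


@pytest.fixture(scope="session")
def assemblage_scenario():
    return syn.default_assemblage_scenario()
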