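import numpy as np
import pytest

import qflow

#: One seed for the shared synthetic cohort used across the suite.
COHORT_SEED = 1234


@pytest.fixture(scope="session")
def instrument():
    return qflow.InstrumentModel()


@pytest.fixture(scope="session")
def default_cohort():
    """The default 23-subject synthetic cohort (generated once per session)."""
    return qflow.generate_cohort(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_result(default_cohort):
    """Full pipeline output (gating, calibration, distributions) for it."""
    return qflow.analyze_cohort(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def identity_curve():
    """A calibration curve with m=1, b=0 (fluorescence == receptors)."""
    levels = tuple((v, v) for v in (474.0, 5359.0, 23843.0, 62336.0))
    return qflow.CalibrationCurve(m=1.0, b=0.0, r_squared=1.0, level_geomeans=levels)
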