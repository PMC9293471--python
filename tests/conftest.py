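import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mesocond import fluorescence, laisk as laisk_mod, variable_j as vj
from mesocond.simulate import (
    TruthParams,
    simulate_calibration_curve,
    simulate_co2_response,
    simulate_laisk_curves,
    laisk_curves_from_records,
)


@pytest.fixture(scope="session")
def truth():
    """Noise-free ground-truth leaf used across recovery tests."""
    return TruthParams()


@pytest.fixture(scope="session")
def established_constants(truth):
    """Genotype-level constants (calibration, Laisk, resolved Gamma*) estimated
    once from the leaf's dedicated noise-free protocols, as a study would."""
    laisk_res = laisk_mod.estimate_laisk(
        laisk_curves_from_records(simulate_laisk_curves(truth)))
    cal = fluorescence.calibrate(simulate_calibration_curve(truth), laisk_res.Rd)
    curve = simulate_co2_response(truth)
    _, resolved = vj.estimate_gm_chain(curve, cal, laisk_res, gamma_star_mode="iterative")
    return {"calibration": cal, "laisk": laisk_res, "resolved": resolved}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
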