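import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qabl.core import InputFunction
from qabl.kinetics import KineticParams
from qabl.simulate import (
    InputFunctionSpec,
    default_frame_schedule,
    dense_time_grid,
    synth_input_function,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def times():
    return dense_time_grid(60.0)


@pytest.fixture(scope="session")
def cp(times):
    """Shared plasma-corrected bolus input on the dense grid."""
    return synth_input_function(InputFunctionSpec(), times, kind="plasma_corrected")


@pytest.fixture(scope="session")
def canonical_params():
    """Reference lung truth used across forward/inverse checks."""
    return KineticParams(K1=0.05, k2=0.4, k3=0.06, vb=0.14, va=0.72)


@pytest.fixture()
def flat_input(times):
    """Constant unit plasma concentration from t = 0 (closed-form checks)."""
    return InputFunction(times, np.ones_like(times), kind="plasma_corrected")
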