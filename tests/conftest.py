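import numpy as np
import pytest

from matreduce.fixtures import RECOVERY_TRUE_PARAMS, mat_recovery_dataset
from matreduce.hh_core import ConductanceParams, steady_state
from matreduce.reduction import ReductionConfig, fit_mat


@pytest.fixture(scope="session")
def defaults():
    return ConductanceParams()


@pytest.fixture(scope="session")
def recovery_fit():
    """Gamma-maximization fit of MAT data with planted parameters."""
    true, cur, sp = mat_recovery_dataset(seed=5, duration=50000.0)
    config = ReductionConfig(
        free=("theta_inf", "alpha_0", "alpha_m"),
        fixed={
            "c_m": 1.0,
            "tau_m": 10.0,
            "tau_ca": 200.0,
            "tau_s_tilde": 50.0,
            "tau_p_vbar": RECOVERY_TRUE_PARAMS["tau_p"],
        },
        seed=3,
    )
    _, cur_test, sp_test = mat_recovery_dataset(seed=6, duration=50000.0)
    fit = fit_mat((cur, sp), config=config, test=(cur_test, sp_test))
    return true, fit


@pytest.fixture(scope="session")
def rest_state(defaults):
    return steady_state(defaults, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
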