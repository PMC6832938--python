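import warnings

import pytest
from hypothesis import HealthCheck, settings

import isebayes as ib

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

# a small MCMC configuration for fast structural tests; numerical-accuracy
# tests choose their own sizes
FAST = ib.MCMCConfig(n_chains=2, n_iter=1500, n_burn=1000, seed=7)


@pytest.fixture
def lead_ctx():
    return ib.ModelContext(z=2, temperature_c=21.0)


@pytest.fixture
def single_sensor():
    return ib.SensorParams(a=100.0, b=29.18, c=1e-6, sigma=0.5)


@pytest.fixture
def calibration_only_dataset(single_sensor):
    cal = ib.simulate_calibration({1: single_sensor}, seed=11)
    return ib.build_dataset(cal, [], ib.Mode.CALIBRATION_ONLY)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Short-chain tests legitimately trip the R-hat warning; keep logs clean."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="R-hat")
        yield
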