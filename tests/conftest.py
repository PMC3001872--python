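import pytest

from adnet import build_default_model, simulate
from adnet.sensitivity import sens_table
from adnet.simulate import simulate_rk4


@pytest.fixture
def default_model():
    return build_default_model()


@pytest.fixture(scope="session")
def baseline_traj():
    """Baseline 20-year trajectory, shared across the suite."""
    return simulate(build_default_model())


@pytest.fixture(scope="session")
def baseline_rk4():
    """Fixed-step RK4 cross-check of the baseline run (dt = 1e-3 yr)."""
    return simulate_rk4(build_default_model(), dt=1e-3)


@pytest.fixture(scope="session")
def full_sensitivity_table():
    """68 rate records + 49 initial-condition records for the default model."""
    return sens_table(build_default_model())
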