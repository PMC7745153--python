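import numpy as np
import pytest

import cudn


@pytest.fixture(scope="session")
def default_schedule():
    return cudn.generate_schedule(cudn.ScheduleConfig(seed=11))


@pytest.fixture(scope="session")
def cudn_session(default_schedule):
    """One CUDN-generated session with typical parameters."""
    return cudn.simulate_session(
        default_schedule,
        cudn.HGFParams(omega=-3.0, theta=0.3),
        cudn.RWParams(alpha=0.25),
        cudn.ResponseParams(beta0=1.5, zeta=0.8, nu=1.0),
        seed=7,
        subject_id="fixture",
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Ten CUDN agents with the default cohort priors (for direction checks)."""
    sessions, truths = cudn.simulate_cohort(10, seed=42)
    return sessions, truths


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
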