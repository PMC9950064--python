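import math

import pytest

from painlearn.hgf_core import HGFParams
from painlearn.psychophysics import PsychometricCurve
from painlearn.response_model import ObsParams, simulate_agent
from painlearn.task_schedule import (
    default_block_compositions,
    derive_trial_intensities,
    generate_schedule,
)


@pytest.fixture(scope="session")
def default_curve():
    """Psychometric curve with a realistic ~0.09 mA threshold scale."""
    return PsychometricCurve(threshold_T=math.log10(0.09))


@pytest.fixture(scope="session")
def default_schedule(default_curve):
    return generate_schedule(
        default_block_compositions(),
        derive_trial_intensities(default_curve),
        seed=3,
    )


@pytest.fixture(scope="session")
def sim_session(default_schedule, default_curve):
    """One simulated agent session with known parameters."""
    session, traj = simulate_agent(
        default_schedule,
        default_curve,
        HGFParams(),
        ObsParams(nu=0.6, beta_slope=8.0),
        seed=5,
    )
    return session, traj
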