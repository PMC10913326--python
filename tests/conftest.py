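import json
from pathlib import Path

import pytest

from collective_cognition import (
    AgentDDMParams,
    Environment,
    RLAgentParams,
    simulate_group,
    simulate_rl_group,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def pilot_tolerances():
    with open(DATA / "recovery_pilot.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def social_ddm_trace():
    """Small socially coupled group trace shared across inference tests."""
    p = AgentDDMParams(delta_p=0.3, s=0.2, threshold_upper=1.0,
                       threshold_lower=-1.0)
    return simulate_group([p] * 5, dt=0.002, t_max=20.0, n_trials=50,
                          seed=1234), p


@pytest.fixture(scope="session")
def rl_weak_conformist_trace():
    """Two replicate groups at the weak-conformist setting."""
    env = Environment(means=(15.0, 20.0), sd=3.0, n_trials=100)
    agents = [RLAgentParams(alpha=0.3, beta=0.18, sigma=0.3, theta=1.5)] * 5
    return simulate_rl_group(agents, env, seed=4321, n_replicates=2), env
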