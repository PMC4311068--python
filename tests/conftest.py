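import numpy as np
import pytest

from stressrl import rw, task


MEDIAN_PARAMS = rw.AgentParams(epsilon=0.62, beta_rew=2.73, beta_pun=0.84)


@pytest.fixture(scope="session")
def median_params() -> rw.AgentParams:
    """Population-median agent parameters used throughout the suite."""
    return MEDIAN_PARAMS


@pytest.fixture(scope="session")
def default_cfg() -> task.TaskConfig:
    return task.TaskConfig()


@pytest.fixture(scope="session")
def median_agent_events(median_params, default_cfg):
    """One full two-session event table from a median-parameter agent."""
    rng = np.random.default_rng(20240917)
    return rw.simulate_agent(median_params, default_cfg, rng)
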