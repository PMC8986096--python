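import numpy as np
import pytest

from odorchoice import (
    ModelParams,
    SessionConfig,
    build_session_schedule,
    simulate_dataset,
)
from odorchoice.task import StaircaseConfig


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams(eta=0.25, gamma=0.8, beta=3.0, persev_p=0.2, lapse=0.02)


@pytest.fixture(scope="session")
def fixed_length_config() -> SessionConfig:
    """Deterministic 80-trial sessions (4 blocks of 20)."""
    return SessionConfig(
        block_length_mean=20, block_length_sd=0, block_length_floor=20
    )


@pytest.fixture(scope="session")
def schedule(fixed_length_config):
    return build_session_schedule(fixed_length_config, seed=11)


@pytest.fixture(scope="session")
def six_state_log(default_params):
    """Eight sessions of closed-loop six-state behavior, one agent."""
    return simulate_dataset("six_state", {"a0": default_params}, 8, seed=101)


@pytest.fixture(scope="session")
def mixed_log():
    """~1,100-trial log from a hybrid-value agent with intermediate w4."""
    p = ModelParams(
        eta=0.3, gamma=0.85, beta=2.5, bias_b=0.1, persev_p=0.15, lapse=0.05, w4=0.5
    )
    return simulate_dataset("hybrid_value", {"a0": p}, 4, seed=77)
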