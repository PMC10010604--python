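"""Shared fixtures: seeded generators and small, fast reference runs."""

from __future__ import annotations

import numpy as np
import pytest

from confinesim import Parameters, RunConfig, run


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


#: Parameters that make a run grow quickly from one cell (frequent, strong
#: drivers) so IO/CLI tests do not sit in the neutral restart phase.
FAST_PARAMS = Parameters(theta_mut=2e-3, theta_fit=0.5, dist="const")
FAST_CONFIG = RunConfig(min_pop=100, max_pop=20_000, seed=7, max_restarts=50_000)


@pytest.fixture(scope="session")
def fast_run():
    """One small accepted run with several clones, shared across IO tests."""
    params = Parameters(theta_mut=2e-3, theta_fit=0.5, theta_conf=0.5, dist="const")
    result = run(params, FAST_CONFIG)
    assert not result.failed
    return result
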