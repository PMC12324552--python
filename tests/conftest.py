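"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from stapaw import environment, simulate


@pytest.fixture(scope="session")
def linear_env():
    return environment.LinearEnvironment()


@pytest.fixture(scope="session")
def paperlike_params():
    return simulate.fixture_params("paperlike-2state")


@pytest.fixture(scope="session")
def small_sim(paperlike_params, linear_env):
    """A small two-state closed-loop simulation (8 tracks x 600 steps)."""
    cfg = simulate.SimConfig(n_tracks=8, n_steps=600, seed=42)
    return simulate.simulate(paperlike_params, linear_env, cfg)


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    return small_sim.to_dataset()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
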