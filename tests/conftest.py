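"""Shared fixtures.

The expensive full-length simulation batteries are session-scoped and
shared between the behavioral tests and the acceptance tests so each
study condition is simulated once.  All replicate seeds are fixed
(base 0), making every stochastic assertion reproducible.
"""

import numpy as np
import pytest

from troopsim import ModelConfig
from troopsim.experiments import run_replicates


@pytest.fixture
def short_config():
    """A fast, structurally complete run (4 snapshots)."""
    return ModelConfig(total_steps=3600.0, burn_in=1800.0,
                       sample_every=450.0)


@pytest.fixture(scope="session")
def fleeing_runs():
    """Ten full-length replicates of the fleeing model, defaults."""
    return run_replicates(ModelConfig(), 10, base_seed=0)


@pytest.fixture(scope="session")
def avoidance_grid():
    """Three replicates of each of the 12 avoidance settings."""
    grid = {}
    for diff in (0.2, 0.4, 0.6):
        for dist in (5.0, 15.0, 25.0, 35.0):
            cfg = ModelConfig(variant="avoidance", av_dom_diff=diff,
                              av_dist=dist)
            grid[(diff, dist)] = run_replicates(cfg, 3, base_seed=0)
    return grid


@pytest.fixture(scope="session")
def avoidance_corner_runs():
    """Ten replicates of the two headline avoidance settings."""
    return {
        (0.6, 5.0): run_replicates(
            ModelConfig(variant="avoidance", av_dom_diff=0.6, av_dist=5.0),
            10, base_seed=0),
        (0.2, 35.0): run_replicates(
            ModelConfig(variant="avoidance", av_dom_diff=0.2, av_dist=35.0),
            10, base_seed=0),
    }


@pytest.fixture(scope="session")
def control_corner_runs():
    """Ten replicates of the fleeing-control corners (win chance 0.5)."""
    return {
        (0.6, 5.0): run_replicates(
            ModelConfig(variant="avoidance_fleeing_control",
                        av_dom_diff=0.6, av_dist=5.0), 10, base_seed=0),
        (0.2, 35.0): run_replicates(
            ModelConfig(variant="avoidance_fleeing_control",
                        av_dom_diff=0.2, av_dist=35.0), 10, base_seed=0),
    }


@pytest.fixture(scope="session")
def velocity_runs():
    """Velocity-model replicates over MAX_VELOCITY plus the equal-speed
    null control."""
    out = {}
    for mv in (1.0, 10.0, 30.0):
        out[mv] = run_replicates(
            ModelConfig(variant="velocity", max_velocity=mv), 4,
            base_seed=0)
    out["equal"] = run_replicates(
        ModelConfig(variant="velocity", max_velocity=30.0,
                    equal_velocities=True), 4, base_seed=0)
    return out


@pytest.fixture(scope="session")
def uniform_timing_runs():
    """Fleeing model under the uniform (0, 20) waiting-time regime."""
    return run_replicates(ModelConfig(timing_regime="uniform"), 5,
                          base_seed=0)
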