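"""Shared fixtures: small simulated trials reused across test modules."""

import warnings

import numpy as np
import pytest

from enrichjm.params import JointModelParams
from enrichjm.simulate import simulate_trial, snapshot_at_event_count


@pytest.fixture(scope="session")
def base_params():
    return JointModelParams()


@pytest.fixture(scope="session")
def alt_trial(base_params):
    """One mid-sized trial under the design alternative (theta1 = -0.5)."""
    rng = np.random.default_rng(2024)
    return simulate_trial(base_params, 2000, theta_overrides=(-0.5, 0.0), rng=rng)


@pytest.fixture(scope="session")
def alt_snapshot(alt_trial):
    """Snapshot of the alternative-scenario trial at 200 subgroup-1 events."""
    return snapshot_at_event_count(alt_trial, 1, 200, 1)


@pytest.fixture(autouse=True)
def _quiet_small_sample_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*events.*recommended for reliable asymptotics.*"
        )
        warnings.filterwarnings("ignore", message=".*calibration fits dropped.*")
        yield
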