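"""Shared fixtures: one set of cached trajectories and series."""

import numpy as np
import pytest

from gridtrack.linearize import unwrap_cumulative_angle
from gridtrack.synth import BehaviorParams, GroundTruth, simulate_trajectory

RADIUS = 75.0
CIRCUMFERENCE = 2.0 * np.pi * RADIUS


@pytest.fixture(scope="session")
def track_traj():
    """Default 600 s track trajectory, seed 0."""
    return simulate_trajectory(BehaviorParams.track(seed=0))


@pytest.fixture(scope="session")
def track_series(track_traj):
    return unwrap_cumulative_angle(track_traj, radius=RADIUS)


@pytest.fixture(scope="session")
def short_traj():
    """Short (120 s) track trajectory for cheap tests."""
    return simulate_trajectory(BehaviorParams.track(seed=1, duration=120))


@pytest.fixture(scope="session")
def short_series(short_traj):
    return unwrap_cumulative_angle(short_traj, radius=RADIUS)


@pytest.fixture(scope="session")
def arena_traj():
    """600 s arena trajectory for 2D map tests."""
    return simulate_trajectory(BehaviorParams.arena(seed=2))


@pytest.fixture(scope="session")
def pi_cell(track_traj):
    """Path-integrated cell, spacing 150 cm, on the default trajectory."""
    from gridtrack.synth import generate_track_spikes
    gt = GroundTruth(coding_model="path_integrated", spacing=150.0)
    spikes = generate_track_spikes(track_traj, gt, seed=10,
                                   circumference=CIRCUMFERENCE,
                                   reference_radius=RADIUS)
    return gt, spikes
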