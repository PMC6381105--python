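"""Cumulative-distance unwrapping, lap segmentation and linearization."""

import numpy as np
import pytest

from gridtrack.core import InputError, ParameterError, Trajectory
from gridtrack.linearize import (
    directional_split,
    lap_position_matrix,
    linearize_activity,
    segment_laps,
    unwrap_cumulative_angle,
)
from gridtrack.core import SpikeTrain
from tests.conftest import CIRCUMFERENCE, RADIUS


def circle_trajectory(n_laps, n=2000, radius=RADIUS, clockwise=True,
                      duration=100.0):
    t = np.linspace(0.0, duration, n)
    sign = -1.0 if clockwise else 1.0
    theta = sign * 2.0 * np.pi * n_laps * t / duration
    return Trajectory(t=t, x1=radius * np.cos(theta),
                      y1=radius * np.sin(theta))


def test_one_clockwise_lap_equals_circumference():
    traj = circle_trajectory(1.0, clockwise=True)
    series = unwrap_cumulative_angle(traj, radius=RADIUS)
    assert series.signed[-1] == pytest.approx(CIRCUMFERENCE, abs=0.01)
    assert series.absolute[-1] == pytest.approx(CIRCUMFERENCE, abs=0.01)


def test_counterclockwise_lap_is_negative():
    traj = circle_trajectory(1.0, clockwise=False)
    series = unwrap_cumulative_angle(traj, radius=RADIUS)
    assert series.signed[-1] == pytest.approx(-CIRCUMFERENCE, abs=0.01)
    assert series.absolute[-1] == pytest.approx(CIRCUMFERENCE, abs=0.01)


def test_stationary_trajectory_accumulates_nothing():
    t = np.linspace(0, 10, 500)
    traj = Trajectory(t=t, x1=np.full(500, RADIUS), y1=np.zeros(500))
    series = unwrap_cumulative_angle(traj, radius=RADIUS)
    assert np.all(series.signed == 0)
    assert np.all(series.absolute == 0)
    assert np.all(series.direction == 0)


def test_center_sample_rejected():
    t = np.linspace(0, 1, 10)
    x = np.full(10, RADIUS)
    x[5] = 0.0
    with pytest.raises(InputError):
        unwrap_cumulative_angle(Trajectory(t=t, x1=x, y1=np.zeros(10)))


def test_signed_distance_matches_independent_summation(track_traj):
    # brute-force oracle: per-sample-pair -R * wrapped angle difference
    series = unwrap_cumulative_angle(track_traj, radius=RADIUS)
    ang = np.arctan2(track_traj.y1, track_traj.x1)
    d = np.diff(ang)
    d = (d + np.pi) % (2 * np.pi) - np.pi
    brute_signed = np.concatenate(([0.0], np.cumsum(-RADIUS * d)))
    brute_abs = np.concatenate(([0.0], np.cumsum(RADIUS * np.abs(d))))
    assert np.allclose(series.signed, brute_signed, atol=1e-6)
    assert np.allclose(series.absolute, brute_abs, atol=1e-6)


def test_lap_segmentation_crossings():
    traj = circle_trajectory(950.0 / CIRCUMFERENCE, clockwise=True)
    series = unwrap_cumulative_angle(traj, radius=RADIUS)
    ids = np.unique(segment_laps(series, CIRCUMFERENCE))
    assert list(ids) == [0, 1, 2]          # 950 cm spans three lap segments
    ccw = circle_trajectory(0.6, clockwise=False)
    ids_ccw = np.unique(segment_laps(
        unwrap_cumulative_angle(ccw, radius=RADIUS), CIRCUMFERENCE))
    # starts at distance 0 (lap 0), then negative distances get lap -1
    assert list(ids_ccw) == [-1, 0]


def test_lap_segmentation_rejects_bad_circumference(track_series):
    with pytest.raises(ParameterError):
        segment_laps(track_series, 0.0)


def test_linearization_conserves_mass(track_series, pi_cell):
    _, spikes = pi_cell
    for frame in ("path_integrated", "travelled", "time"):
        prof = linearize_activity(spikes, track_series, frame)
        assert prof.counts.sum() == pytest.approx(spikes.n_spikes)
        duration = track_series.t[-1] - track_series.t[0]
        assert prof.occupancy.sum() == pytest.approx(duration, rel=0.01)


def test_pi_profile_periodicity_recovered(track_series, pi_cell):
    from gridtrack.coding import autocorrelation_1d
    _, spikes = pi_cell
    prof = linearize_activity(spikes, track_series, "path_integrated")
    ac = autocorrelation_1d(prof)
    assert ac.first_peak_lag == pytest.approx(150.0, abs=10.0)


def test_unknown_frame_rejected(track_series, pi_cell):
    with pytest.raises(ParameterError):
        linearize_activity(pi_cell[1], track_series, "banana")


def test_lap_matrix_conserves_mass(track_series, pi_cell):
    _, spikes = pi_cell
    lm = lap_position_matrix(spikes, track_series, CIRCUMFERENCE)
    duration = track_series.t[-1] - track_series.t[0]
    assert lm.occupancy.sum() == pytest.approx(duration, rel=0.01)
    assert lm.counts.sum() == pytest.approx(spikes.n_spikes, abs=2)
    assert lm.bin_width == pytest.approx(CIRCUMFERENCE / 47)


def test_lap_matrix_needs_two_laps():
    from gridtrack.linearize import InsufficientDataError
    traj = circle_trajectory(0.4, clockwise=True)
    series = unwrap_cumulative_angle(traj, radius=RADIUS)
    with pytest.raises(InsufficientDataError):
        lap_position_matrix(SpikeTrain(times=np.array([1.0, 2.0, 3.0])),
                            series, CIRCUMFERENCE)


def test_directional_split_allocentric_cell(track_traj, track_series):
    from gridtrack.synth import GroundTruth, generate_track_spikes
    gt = GroundTruth(coding_model="allocentric", spacing=120.0,
                     peak_rate=20.0)
    spikes = generate_track_spikes(track_traj, gt, seed=21,
                                   circumference=CIRCUMFERENCE,
                                   reference_radius=RADIUS)
    cw, ccw, r = directional_split(spikes, track_series)
    assert cw.frame == "path_integrated" and ccw.frame == "path_integrated"
    assert np.isfinite(r)
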