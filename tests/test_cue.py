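"""Cue-card visibility geometry, region stability, light/dark analyses."""

import numpy as np
import pytest

from gridtrack.core import ParameterError
from gridtrack.cue import (
    Arc,
    RegionPartition,
    TrackGeometry,
    field_angles,
    field_density_by_region,
    light_dark_comparison,
    profile_correlation,
    region_partition,
    region_stability,
    stability_paired_test,
    track_position_profile,
    visible_arc,
    visible_arc_raycast,
)
from gridtrack.linearize import InsufficientDataError
from gridtrack.synth import (
    BehaviorParams,
    GroundTruth,
    generate_drifting_spikes,
    generate_track_spikes,
    simulate_trajectory,
)
from tests.conftest import CIRCUMFERENCE, RADIUS


GEOMETRIES = [
    TrackGeometry(),
    TrackGeometry(radius_outer=75.0, radius_inner=50.0, radius_mid=62.5,
                  card_width_cm=50.0, card_angle_deg=30.0),
    TrackGeometry(radius_outer=100.0, radius_inner=85.0, radius_mid=92.5,
                  card_width_cm=20.0, card_angle_deg=200.0),
]


@pytest.mark.parametrize("convention", ["any-point", "whole-card"])
@pytest.mark.parametrize("geom", GEOMETRIES)
def test_analytic_arc_matches_raycast(geom, convention):
    a = visible_arc(geom, convention)
    b = visible_arc_raycast(geom, convention, angle_step_deg=0.25,
                            card_step_cm=0.25)
    assert a.extent_deg == pytest.approx(b.extent_deg, abs=2.0)
    assert a.center_deg == geom.card_angle_deg % 360.0


def test_no_inner_wall_means_card_visible_everywhere():
    geom = TrackGeometry(radius_inner=0.0, radius_mid=60.0,
                         radius_outer=75.0)
    assert visible_arc(geom, "any-point").extent_deg == pytest.approx(360.0)


def test_visible_arc_monotonicity():
    narrow = visible_arc(TrackGeometry(card_width_cm=10.0))
    wide = visible_arc(TrackGeometry(card_width_cm=60.0))
    assert wide.extent_deg > narrow.extent_deg
    open_ = visible_arc(TrackGeometry(radius_inner=40.0))
    closed = visible_arc(TrackGeometry(radius_inner=60.0))
    assert open_.extent_deg > closed.extent_deg


def test_geometry_validation():
    with pytest.raises(ParameterError):
        TrackGeometry(radius_inner=70.0, radius_mid=65.0)
    with pytest.raises(ParameterError):
        TrackGeometry(card_width_cm=-1.0)


def test_partition_arithmetic_160():
    p = region_partition(visible=Arc(90.0, 160.0))
    assert p.visible.extent_deg == pytest.approx(160.0)
    assert p.nonvisible.extent_deg == pytest.approx(160.0)
    assert p.buffer_deg == pytest.approx(40.0)
    assert p.nonvisible.center_deg == pytest.approx(270.0)
    assert p.visible_arc_deg == pytest.approx(160.0)


def test_partition_arithmetic_180_and_200():
    p = region_partition(visible=Arc(0.0, 180.0))
    assert p.buffer_deg == pytest.approx(0.0)
    # a visible arc over half the track trims to its complement
    p = region_partition(visible=Arc(0.0, 200.0))
    assert p.visible.extent_deg == pytest.approx(160.0)
    assert p.buffer_deg == pytest.approx(40.0)


def test_overlapping_regions_rejected():
    with pytest.raises(ParameterError):
        RegionPartition(visible=Arc(0.0, 200.0), nonvisible=Arc(180.0, 200.0),
                        visible_arc_deg=200.0, buffer_deg=-40.0)


PARTITION = region_partition(visible=Arc(90.0, 160.0))


def test_field_density_chi2_oracles():
    # seven fields, all in the visible region: chi2 = (7-3.5)^2/3.5 * 2 = 7
    fd = field_density_by_region([90.0] * 7, PARTITION)
    assert fd.n_visible == 7 and fd.n_nonvisible == 0
    assert fd.chi2 == pytest.approx(7.0)
    # perfectly balanced split
    fd = field_density_by_region([80.0, 100.0, 260.0, 280.0], PARTITION)
    assert fd.chi2 == pytest.approx(0.0)
    assert fd.p == pytest.approx(1.0)
    # buffer fields are excluded but counted
    fd = field_density_by_region([90.0, 270.0, 0.0], PARTITION)
    assert fd.n_excluded == 1


def test_field_density_degenerate_inputs():
    with pytest.raises(InsufficientDataError):
        field_density_by_region([], PARTITION)
    with pytest.raises(InsufficientDataError):
        field_density_by_region([0.0, 180.0], PARTITION)


def test_field_angles_match_generative_centres(track_traj):
    # sigma 20 cm keeps each field above the 5-bin detection minimum
    gt = GroundTruth(coding_model="allocentric", first_offset=50.0,
                     spacing=CIRCUMFERENCE / 4.0, peak_rate=10.0,
                     field_width=20.0)
    spikes = generate_track_spikes(track_traj, gt, seed=30,
                                   circumference=CIRCUMFERENCE,
                                   reference_radius=RADIUS)
    found = np.sort(field_angles(spikes, track_traj, radius=RADIUS))
    centres = np.mod(50.0 + (CIRCUMFERENCE / 4.0) * np.arange(4),
                     CIRCUMFERENCE)
    # the generator folds signed distance from the session start; shift
    # the centres into the room-anchored fold used by field_angles
    theta0 = np.arctan2(track_traj.y1[0], track_traj.x1[0])
    room = np.mod(centres - RADIUS * theta0, CIRCUMFERENCE)
    expected = np.sort(np.degrees(-room / RADIUS) % 360.0)
    assert found.size == 4
    d = np.abs((found - expected + 180.0) % 360.0 - 180.0)
    assert d.max() < 8.0


def test_profile_correlation_identity_and_binning(track_traj, pi_cell):
    prof = track_position_profile(pi_cell[1], track_traj, radius=RADIUS)
    assert profile_correlation(prof, prof) == pytest.approx(1.0)
    other = track_position_profile(pi_cell[1], track_traj, bin_width=5.0,
                                   radius=RADIUS)
    with pytest.raises(ParameterError):
        profile_correlation(prof, other)


def test_light_dark_identical_sessions(track_traj, pi_cell):
    res = light_dark_comparison((pi_cell[1], track_traj),
                                (pi_cell[1], track_traj),
                                (pi_cell[1], track_traj), radius=RADIUS)
    assert res.r_light_light == pytest.approx(1.0, abs=1e-6)
    assert res.r_light_dark == pytest.approx(1.0, abs=1e-4)
    with pytest.raises(InsufficientDataError):
        light_dark_comparison((pi_cell[1], track_traj), None,
                              (pi_cell[1], track_traj))


def test_light_sessions_more_similar_than_dark():
    gt = GroundTruth(coding_model="allocentric", first_offset=40.0,
                     spacing=CIRCUMFERENCE / 3.0, peak_rate=10.0)
    r_ll, r_ld = [], []
    for s in range(6):
        trajs = [simulate_trajectory(BehaviorParams.track(
            seed=100 + 10 * s + k, duration=300.0)) for k in range(3)]
        light1 = generate_drifting_spikes(trajs[0], gt, seed=200 + s,
                                          noise_sd=3.0, anchoring=0.8,
                                          reference_radius=RADIUS)
        dark = generate_drifting_spikes(trajs[1], gt, seed=300 + s,
                                        noise_sd=25.0, anchoring=0.1,
                                        reference_radius=RADIUS)
        light2 = generate_drifting_spikes(trajs[2], gt, seed=400 + s,
                                          noise_sd=3.0, anchoring=0.8,
                                          reference_radius=RADIUS)
        res = light_dark_comparison((light1, trajs[0]), (dark, trajs[1]),
                                    (light2, trajs[2]), radius=RADIUS)
        r_ll.append(res.r_light_light)
        r_ld.append(res.r_light_dark)
    assert np.mean(r_ll) > np.mean(r_ld)


def test_stability_paired_test_oracles():
    t, p = stability_paired_test([(0.8, 0.2), (0.7, 0.1), (0.9, 0.3),
                                  (0.75, 0.15), (0.85, 0.2)])
    assert t > 0 and p < 0.01
    from gridtrack.core import InputError
    with pytest.raises(InputError):
        stability_paired_test([(0.5, 0.4)])


def test_region_stability_detects_regional_drift():
    # random-walk field drift confined to the non-visible region: the
    # pooled profile there decorrelates while the visible region stays
    # periodic, so the paired comparison must come out positive
    gt = GroundTruth(coding_model="allocentric", first_offset=30.0,
                     spacing=CIRCUMFERENCE / 4.0, peak_rate=12.0,
                     field_width=8.0)
    from gridtrack.linearize import unwrap_cumulative_angle
    pairs = []
    for s in range(16):
        traj = simulate_trajectory(BehaviorParams.track(seed=500 + s,
                                                        duration=600.0))
        series = unwrap_cumulative_angle(traj, radius=RADIUS)
        spikes = generate_drifting_spikes(
            traj, gt, seed=600 + s, noise_sd=30.0, anchoring=0.0,
            noise_region=PARTITION.nonvisible, reference_radius=RADIUS)
        try:
            pairs.append(region_stability(spikes, traj, series, PARTITION))
        except InsufficientDataError:
            continue
    assert len(pairs) >= 12
    t, p = stability_paired_test(pairs)
    assert t > 0
    assert p < 0.05
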