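"""1D autocorrelations, lap-shift correction, jitter nulls, classification."""

import numpy as np
import pytest

from gridtrack.core import GridtrackError, ParameterError, SpikeTrain
from gridtrack.coding import (
    allocentric_correlation,
    autocorrelation_1d,
    classify_cell,
    field_distance_from_autocorr,
    fisher_z,
    fisher_z_inverse,
    jitter_null,
    jitter_statistics,
    mean_correlation,
    path_integrated_correlation,
    split_half_control,
)
from gridtrack.linearize import LapMatrix, LinearizedActivity, linearize_activity
from gridtrack.synth import GroundTruth, generate_track_spikes
from tests.conftest import CIRCUMFERENCE, RADIUS


def periodic_profile(period=100.0, bw=10.0, nbins=100, sigma=8.0):
    edges = bw * np.arange(nbins + 1)
    c = 0.5 * (edges[:-1] + edges[1:])
    d = np.mod(c - 30.0, period)
    d = np.minimum(d, period - d)
    counts = 50.0 * np.exp(-d * d / (2 * sigma * sigma))
    return LinearizedActivity(frame="path_integrated", bin_width=bw,
                              edges=edges, counts=counts,
                              occupancy=np.ones(nbins))


def test_autocorrelation_recovers_period():
    ac = autocorrelation_1d(periodic_profile())
    assert ac.values[0] == pytest.approx(1.0, abs=1e-9)
    assert ac.first_peak_lag == pytest.approx(100.0, abs=10.0)
    assert ac.mean_first_two > 0.9


def test_constant_profile_rejected():
    prof = LinearizedActivity(frame="path_integrated", bin_width=10.0,
                              edges=10.0 * np.arange(101),
                              counts=np.full(100, 5.0),
                              occupancy=np.ones(100))
    with pytest.raises(GridtrackError):
        autocorrelation_1d(prof)


def test_field_distance_threshold_fallback():
    ac = autocorrelation_1d(periodic_profile())
    # stricter threshold than any peak value falls back to the 0.1 floor
    assert field_distance_from_autocorr(ac, threshold=0.99) \
        == pytest.approx(ac.first_peak_lag)


def test_fisher_z_oracles():
    assert fisher_z(0.6) == pytest.approx(0.6931, abs=2e-4)
    assert fisher_z(0.0) == 0.0
    for r in (-0.8, -0.2, 0.5, 0.95):
        assert fisher_z_inverse(fisher_z(r)) == pytest.approx(r, abs=1e-9)
    assert np.isfinite(fisher_z(1.0))
    with pytest.raises(ParameterError):
        fisher_z(1.5)


def test_mean_correlation_of_identical_values():
    assert mean_correlation([0.4, 0.4, 0.4]) == pytest.approx(0.4, abs=1e-9)
    assert np.isnan(mean_correlation([np.nan]))


def _lapmat(rows):
    rows = np.asarray(rows, dtype=float)
    return LapMatrix(rates=rows, occupancy=np.ones_like(rows),
                     counts=rows, lap_ids=np.arange(rows.shape[0]),
                     circumference=CIRCUMFERENCE)


def test_identical_laps_fully_correlated():
    row = np.sin(np.linspace(0, 4 * np.pi, 47)) + 2.0
    lm = _lapmat([row, row, row])
    # Fisher-Z averaging clips |r| = 1 at 0.999999
    assert allocentric_correlation(lm) == pytest.approx(1.0, abs=2e-6)


def test_correction_beats_uncorrected_for_pi_cell(track_series, pi_cell):
    from gridtrack.linearize import lap_position_matrix
    gt, spikes = pi_cell
    lm = lap_position_matrix(spikes, track_series, CIRCUMFERENCE)
    alloc = allocentric_correlation(lm)
    corr = path_integrated_correlation(lm, gt.spacing)
    assert corr.mean_r > alloc
    assert corr.residual == pytest.approx(CIRCUMFERENCE % 150.0, abs=1e-9)


def test_divisor_spacing_correction_is_identity(track_traj, track_series):
    from gridtrack.linearize import lap_position_matrix
    gt = GroundTruth(coding_model="path_integrated",
                     spacing=CIRCUMFERENCE / 3.0)
    spikes = generate_track_spikes(track_traj, gt, seed=22,
                                   reference_radius=RADIUS)
    lm = lap_position_matrix(spikes, track_series, CIRCUMFERENCE)
    alloc = allocentric_correlation(lm)
    corr = path_integrated_correlation(lm, gt.spacing)
    assert abs(corr.mean_r - alloc) <= 1e-12
    assert abs(corr.residual) <= 1e-9


def test_unusable_field_distance_falls_back(track_series, pi_cell):
    from gridtrack.linearize import lap_position_matrix
    lm = lap_position_matrix(pi_cell[1], track_series, CIRCUMFERENCE)
    res = path_integrated_correlation(lm, float("nan"))
    assert res.fell_back
    assert res.mean_r == pytest.approx(allocentric_correlation(lm))


def test_split_half_control_on_pi_cell(track_series, pi_cell):
    res = split_half_control(pi_cell[1], track_series, CIRCUMFERENCE)
    assert res.field_distance == pytest.approx(150.0, abs=15.0)
    assert res.corrected_r > res.allocentric_r


def test_jitter_statistics_shape_and_determinism(track_series, pi_cell):
    _, spikes = pi_cell
    a = jitter_statistics(spikes, track_series, n=10, seed=5)
    b = jitter_statistics(spikes, track_series, n=10, seed=5)
    for frame in ("path_integrated", "travelled", "time"):
        assert a[frame].size == 10
        assert np.array_equal(a[frame], b[frame], equal_nan=True)


def test_jitter_null_destroys_periodicity(track_series, pi_cell):
    _, spikes = pi_cell
    prof = linearize_activity(spikes, track_series, "path_integrated")
    observed = autocorrelation_1d(prof).mean_first_two
    null = jitter_null(spikes, track_series, "path_integrated", n=30, seed=1)
    assert observed > null.threshold


def test_threshold_monotonic_in_percentile(track_series, pi_cell):
    _, spikes = pi_cell
    n95 = jitter_null(pi_cell[1], track_series, "path_integrated", n=30,
                      percentile=95.0, seed=2)
    n99 = jitter_null(pi_cell[1], track_series, "path_integrated", n=30,
                      percentile=99.0, seed=2)
    assert n99.threshold >= n95.threshold


THRESHOLDS = {"path_integrated": 0.2, "travelled": 0.2, "time": 0.2}


def test_classify_silent_cell_degenerate(track_series):
    cls = classify_cell(SpikeTrain(times=np.array([1.0, 2.0])),
                        track_series, THRESHOLDS, CIRCUMFERENCE)
    assert cls.degenerate
    assert cls.label == "none"


def test_classify_pi_cell(track_series, pi_cell):
    _, spikes = pi_cell
    thresholds = {
        f: jitter_null(spikes, track_series, f, n=30, seed=3).threshold
        for f in ("path_integrated", "travelled", "time")}
    cls = classify_cell(spikes, track_series, thresholds, CIRCUMFERENCE,
                        alloc_n_perm=100, seed=4)
    assert cls.flags["path_integrated"]
    assert cls.label == "path_integrated"
    assert cls.field_distance == pytest.approx(150.0, abs=15.0)
    assert cls.corrected_r > cls.allocentric_r


def test_classify_requires_all_thresholds(track_series, pi_cell):
    with pytest.raises(ParameterError):
        classify_cell(pi_cell[1], track_series,
                      {"path_integrated": 0.2}, CIRCUMFERENCE)
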