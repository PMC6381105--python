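"""Rate maps, autocorrelograms, gridness, field detection."""

import numpy as np
import pytest

from gridtrack.core import SpikeTrain
from gridtrack.maps import (
    RateMap2D,
    autocorr_peaks,
    compute_rate_map,
    detect_fields,
    field_spacing_2d,
    gridness,
    pair_phase_offset,
    spatial_autocorrelogram,
)
from gridtrack.synth import GroundTruth, lattice_rate


def analytic_map(fn, extent=150.0, bin_=2.5):
    """RateMap2D from an analytic rate function on a disc-shaped arena."""
    n = int(round(2 * extent / bin_))
    edges = -extent + bin_ * np.arange(n + 1)
    c = 0.5 * (edges[:-1] + edges[1:])
    xx, yy = np.meshgrid(c, c)
    rate = fn(xx, yy)
    mask = np.hypot(xx, yy) <= extent
    rate = np.where(mask, rate, np.nan)
    return RateMap2D(rate=rate, occupancy=mask.astype(float), mask=mask,
                     bin=bin_, x_edges=edges, y_edges=edges)


@pytest.fixture(scope="module")
def lattice_map():
    gt = GroundTruth(coding_model="slice2d", lattice_spacing=50.0,
                     field_width_2d=8.0, peak_rate=10.0)
    return analytic_map(lambda x, y: lattice_rate(x, y, gt))


def test_occupancy_conserves_duration(arena_traj):
    rm = compute_rate_map(arena_traj, SpikeTrain(times=np.array([1.0, 2.0])))
    assert rm.occupancy.sum() == pytest.approx(arena_traj.duration, rel=0.01)


def test_homogeneous_poisson_rate_recovered(arena_traj):
    rng = np.random.default_rng(0)
    duration = arena_traj.duration
    n = rng.poisson(5.0 * duration)
    spikes = SpikeTrain(times=np.sort(rng.uniform(0, duration, n)))
    rm = compute_rate_map(arena_traj, spikes)
    mean_rate = np.nansum(rm.rate * rm.occupancy) / rm.occupancy.sum()
    assert mean_rate == pytest.approx(5.0, rel=0.10)


def test_no_spike_map_is_zero_and_uncorrelatable(arena_traj):
    from gridtrack.core import InputError
    rm = compute_rate_map(arena_traj, SpikeTrain(times=np.empty(0)))
    assert np.nanmax(rm.rate) == 0.0
    with pytest.raises(InputError):
        spatial_autocorrelogram(rm)


def test_autocorrelogram_center_is_one_and_symmetric(lattice_map):
    ac = spatial_autocorrelogram(lattice_map)
    cy, cx = ac.center
    assert ac.values[cy, cx] == pytest.approx(1.0, abs=1e-9)
    v = ac.values
    flipped = v[::-1, ::-1]
    both = np.isfinite(v) & np.isfinite(flipped)
    assert np.allclose(v[both], flipped[both], atol=1e-9)


def test_autocorrelogram_matches_bruteforce_lag(lattice_map):
    ac = spatial_autocorrelogram(lattice_map)
    cy, cx = ac.center
    dy, dx = 5, -3
    a = lattice_map.rate
    # pairs (a[i+dy, j+dx], a[i, j]) over bins valid in both
    shifted = a[dy:, :]
    base = a[:-dy, :]
    shifted = shifted[:, : dx] if dx < 0 else shifted[:, dx:]
    base = base[:, -dx:] if dx < 0 else base[:, : a.shape[1] - dx]
    both = np.isfinite(shifted) & np.isfinite(base)
    r = np.corrcoef(shifted[both], base[both])[0, 1]
    assert ac.values[cy + dy, cx + dx] == pytest.approx(r, abs=1e-6)


def test_six_inner_peaks_at_lattice_spacing(lattice_map):
    ac = spatial_autocorrelogram(lattice_map)
    peaks = autocorr_peaks(ac)
    assert peaks.shape[0] >= 6
    assert field_spacing_2d(ac) == pytest.approx(50.0, rel=0.10)


def test_ideal_lattice_gridness_high(lattice_map):
    g = gridness(spatial_autocorrelogram(lattice_map))
    assert g >= 1.0


def test_radially_symmetric_map_not_grid():
    rm = analytic_map(
        lambda x, y: np.exp(-((np.hypot(x, y) - 50.0) ** 2) / (2 * 15.0 ** 2)))
    g = gridness(spatial_autocorrelogram(rm))
    assert abs(g) < 0.2


def test_gridness_scale_invariant(lattice_map):
    ac1 = spatial_autocorrelogram(lattice_map)
    doubled = RateMap2D(rate=2.0 * lattice_map.rate,
                        occupancy=lattice_map.occupancy,
                        mask=lattice_map.mask, bin=lattice_map.bin,
                        x_edges=lattice_map.x_edges,
                        y_edges=lattice_map.y_edges)
    ac2 = spatial_autocorrelogram(doubled)
    assert gridness(ac1) == pytest.approx(gridness(ac2), abs=1e-9)


def test_strict_gridness_nan_without_six_peaks():
    rm = analytic_map(lambda x, y: np.exp(-(x * x + y * y) / (2 * 30.0 ** 2)))
    g = gridness(spatial_autocorrelogram(rm), strict=True)
    assert np.isnan(g)


def test_detect_fields_counts():
    x = np.arange(200.0)
    one = np.exp(-((x - 100) ** 2) / (2 * 8.0 ** 2))
    two = one + np.exp(-((x - 40) ** 2) / (2 * 8.0 ** 2))
    assert detect_fields(one).n_fields == 1
    assert detect_fields(two).n_fields == 2
    assert detect_fields(np.zeros(200)).n_fields == 0
    # a 3-bin blip is below the 5-pixel minimum
    blip = np.zeros(200)
    blip[50:53] = 1.0
    assert detect_fields(blip).n_fields == 0


def test_detect_fields_centroid():
    x = np.arange(200.0)
    fs = detect_fields(np.exp(-((x - 120) ** 2) / (2 * 8.0 ** 2)))
    assert fs.fields[0].centroid[0] == pytest.approx(120.0, abs=1.0)


def _train_profile(shift):
    from gridtrack.linearize import LinearizedActivity
    bw = 5.0
    edges = bw * np.arange(201)
    c = 0.5 * (edges[:-1] + edges[1:])
    d = np.mod(c - 50.0 - shift, 100.0)
    d = np.minimum(d, 100.0 - d)
    counts = 40.0 * np.exp(-d * d / (2 * 8.0 ** 2))
    return LinearizedActivity(frame="path_integrated", bin_width=bw,
                              edges=edges, counts=counts,
                              occupancy=np.ones(200))


def test_pair_phase_offset_track():
    a = _train_profile(0.0)
    assert pair_phase_offset(a, a, environment="track") \
        == pytest.approx(0.0, abs=1e-9)
    b = _train_profile(30.0)
    off = pair_phase_offset(a, b, environment="track")
    assert off == pytest.approx(30.0, abs=5.0)
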