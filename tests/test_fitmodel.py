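"""Gaussian spike-train model: profile prediction, scoring, fitting."""

import numpy as np
import pytest

from gridtrack.fitmodel import (
    TrainModelParams,
    differential_evolution,
    compare_distance_methods,
    fit_cell,
    fit_score,
    observed_profile,
    predict_profile,
    reconstruct_map,
)
from gridtrack.linearize import LinearizedActivity


def make_profile(spacing=150.0, width=10.0, offset=40.0, extent=4500.0,
                 bw=10.0, total=800.0):
    """Noise-free count-density profile of a Gaussian train."""
    edges = bw * np.arange(int(extent / bw) + 1)
    c = 0.5 * (edges[:-1] + edges[1:])
    k = np.arange(int(np.ceil(extent / spacing)) + 1)
    d = c[:, None] - (offset + spacing * k[None, :])
    prof = np.exp(-d * d / (2 * width * width)).sum(axis=1)
    counts = prof * (total / prof.sum())
    return LinearizedActivity(frame="path_integrated", bin_width=bw,
                              edges=edges, counts=counts,
                              occupancy=np.ones(c.size))


def test_predicted_profile_integral_matches_spike_count():
    prof = make_profile()
    p = TrainModelParams(width=10.0, first_offset=40.0, spacing=150.0)
    pred = predict_profile(p, prof.centers, 800.0,
                           occupancy=prof.occupancy)
    assert pred.sum() * prof.bin_width == pytest.approx(800.0, rel=1e-3)


def test_predicted_profile_translation_symmetry():
    prof = make_profile()
    c = prof.centers
    p1 = TrainModelParams(width=10.0, first_offset=40.0, spacing=150.0)
    p2 = TrainModelParams(width=10.0, first_offset=240.0, spacing=150.0)
    a = predict_profile(p1, c, 100.0)
    b = predict_profile(p2, c + 200.0, 100.0)
    assert np.allclose(a, b, atol=1e-9)


def test_single_field_when_spacing_exceeds_extent():
    c = 10.0 * np.arange(100) + 5.0
    p = TrainModelParams(width=30.0, first_offset=500.0, spacing=5000.0)
    pred = predict_profile(p, c, 50.0)
    from gridtrack.maps import detect_fields
    assert detect_fields(pred).n_fields == 1


def test_fit_score_zero_at_truth_and_worse_nearby():
    prof = make_profile()
    obs = observed_profile(prof)
    from scipy import ndimage
    occ_w = ndimage.gaussian_filter1d(prof.occupancy, 1.0)
    truth = TrainModelParams(width=10.0, first_offset=40.0, spacing=150.0)

    def score(p):
        return fit_score(obs, p, prof.centers, prof.counts.sum(),
                         prof.occupied, occupancy=occ_w)

    # observed profile is smoothed with a one-bin kernel: the matching
    # model width is sqrt(10^2 + 10^2)
    smoothed = TrainModelParams(width=np.sqrt(200.0), first_offset=40.0,
                                spacing=150.0)
    s0 = score(smoothed)
    assert s0 < 0.02 * score(truth) + 1.0
    for factor in (0.8, 1.2):
        off = TrainModelParams(width=np.sqrt(200.0), first_offset=40.0,
                               spacing=150.0 * factor)
        assert score(off) > 10.0 * max(s0, 1e-9)


def test_differential_evolution_minimizes_sphere():
    res = differential_evolution(lambda x: float(np.sum(np.square(x))),
                                 [(-5, 5), (-5, 5)], seed=0)
    assert res.fun < 1e-6


def test_fit_recovers_parameters():
    prof = make_profile(spacing=150.0, width=10.0, offset=40.0)
    res = fit_cell(prof, seed=0)
    assert res.params.spacing == pytest.approx(150.0, rel=0.10)
    # the first-train position is identified modulo the spacing
    d = (res.params.first_offset - 40.0) % res.params.spacing
    d = min(d, res.params.spacing - d)
    assert d <= 15.0


def test_fit_deterministic():
    prof = make_profile(spacing=120.0, width=8.0, offset=70.0)
    a = fit_cell(prof, seed=3)
    b = fit_cell(prof, seed=3)
    assert a.params.spacing == b.params.spacing
    assert a.ssd == b.ssd


def test_degenerate_profile_rejected():
    from gridtrack.linearize import InsufficientDataError
    flat = LinearizedActivity(frame="path_integrated", bin_width=10.0,
                              edges=10.0 * np.arange(101),
                              counts=np.zeros(100),
                              occupancy=np.ones(100))
    with pytest.raises(InsufficientDataError):
        fit_cell(flat)


def test_compare_distance_methods_identity():
    r, p = compare_distance_methods([80.0, 120.0, 150.0, 200.0],
                                    [80.0, 120.0, 150.0, 200.0])
    assert r == pytest.approx(1.0, abs=1e-9)
    from gridtrack.linearize import InsufficientDataError
    with pytest.raises(InsufficientDataError):
        compare_distance_methods([1.0, np.nan], [1.0, 2.0])


def test_reconstructed_map_matches_observed(track_traj, track_series,
                                            pi_cell):
    from gridtrack.linearize import linearize_activity
    from gridtrack.maps import compute_rate_map
    _, spikes = pi_cell
    prof = linearize_activity(spikes, track_series, "path_integrated")
    res = fit_cell(prof, seed=1)
    observed = compute_rate_map(track_traj, spikes)
    _, r = reconstruct_map(res, track_traj, track_series,
                           observed_map=observed)
    assert r > 0.5
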