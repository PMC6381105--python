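"""Spatial spectral analysis: is track firing 1D-periodic or a 2D slice?

A cell whose track firing is a straight slice through its 2D hexagonal
lattice produces a spatial power spectrum with up to three comparable
peaks (one per lattice axis), whereas genuinely one-dimensional periodic
firing concentrates power in a single peak. The *one-peakness* score —
area under the highest spectral peak divided by the total spectral area
— quantifies this; it is compared against the null distribution of
scores obtained by sliding the animal's real track path across the 2D
lattice (the "fake track" construction).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import signal

from .core import InputError, ParameterError, SpikeTrain, Trajectory
from .linearize import (
    CumulativeDistanceSeries,
    InsufficientDataError,
    LinearizedActivity,
)

PSD_BIN = 2.5           # cm; finer than analysis bins to resolve slice spectra
PSD_SMOOTH_BINS = 6.0   # Gaussian sigma (bins, = 15 cm) before the transform
MIN_BINS = 64
TRACK_ARENA_SPACING_RATIO = 1.85   # field distance (track) / lattice spacing


@dataclass
class SpectrumResult:
    """Spatial power spectral density with its one-peakness score."""

    frequencies: np.ndarray    # cycles/cm
    power: np.ndarray
    score: float = float("nan")
    peak_interval: Tuple[float, float] = (float("nan"), float("nan"))
    signal_variance: float = float("nan")   # variance of the transformed profile

    @property
    def is_flat(self) -> bool:
        return bool(np.all(self.power <= 1e-15 * max(1.0, self.power.max(initial=0.0))))

    @property
    def peak_frequency(self) -> float:
        if self.is_flat:
            return float("nan")
        return float(self.frequencies[np.argmax(self.power)])


@dataclass
class SliceNull:
    """Null distribution of one-peakness scores from fake tracks."""

    lattice: dict              # lattice parameters used
    scores: np.ndarray         # one score per path shift
    percentile: float = 95.0

    @property
    def threshold(self) -> float:
        return float(np.nanpercentile(self.scores, self.percentile))


def profile_for_psd(spikes: SpikeTrain, series: CumulativeDistanceSeries,
                    bin_width: float = PSD_BIN) -> LinearizedActivity:
    """Path-integrated profile at the fine spectral bin width."""
    from .linearize import linearize_activity
    return linearize_activity(spikes, series, "path_integrated", bin_width)


def _gap_filled_rate(profile: LinearizedActivity) -> np.ndarray:
    """Firing rate with unoccupied bins linearly interpolated."""
    rate = profile.rate
    occ = profile.occupied
    if not occ.any():
        raise InputError("profile has no occupied bins")
    idx = np.arange(rate.size)
    return np.interp(idx, idx[occ], rate[occ])


def psd(profile: LinearizedActivity,
        smooth_bins: float = PSD_SMOOTH_BINS) -> SpectrumResult:
    """Mean-subtracted periodogram of the linearized firing rate.

    The rate is gap-filled and Gaussian-smoothed (``smooth_bins`` bins;
    0 disables) before the transform, suppressing the Poisson noise
    floor that otherwise swamps the periodic peak. The total spectral
    power (integral over frequency) equals the variance of the
    transformed profile (Parseval; exposed as ``signal_variance``).
    Requires at least 64 bins; the score field is left unset.
    """
    if profile.counts.size < MIN_BINS:
        raise InsufficientDataError(
            f"profile has {profile.counts.size} bins; need >= {MIN_BINS}")
    x = _gap_filled_rate(profile)
    if smooth_bins > 0:
        from scipy import ndimage
        x = ndimage.gaussian_filter1d(x, smooth_bins)
    freqs, power = signal.periodogram(
        x, fs=1.0 / profile.bin_width, window="boxcar",
        detrend="constant", scaling="density")
    return SpectrumResult(frequencies=freqs, power=power,
                          signal_variance=float(np.var(x)))


def one_peakness(spectrum: SpectrumResult,
                 rule: str = "local-min") -> SpectrumResult:
    """Area under the highest spectral peak over the total area.

    The peak interval runs between the two local minima flanking the
    global maximum (``rule="local-min"``), or between the half-maximum
    crossings (``rule="half-max"``). The zero-frequency bin is excluded
    from the peak search (the spectrum is mean-subtracted). Returns a
    new SpectrumResult with score and peak interval set.
    """
    if rule not in ("local-min", "half-max"):
        raise ParameterError(f"unknown rule {rule!r}")
    p = spectrum.power
    total = p.sum()
    if total <= 0 or spectrum.is_flat:
        raise InputError("zero-power spectrum: one-peakness undefined")
    j = 1 + int(np.argmax(p[1:]))
    lo = j
    if rule == "local-min":
        while lo > 1 and p[lo - 1] <= p[lo]:
            lo -= 1
        hi = j
        while hi < p.size - 1 and p[hi + 1] <= p[hi]:
            hi += 1
    else:
        half = 0.5 * p[j]
        lo = j
        while lo > 1 and p[lo - 1] >= half:
            lo -= 1
        hi = j
        while hi < p.size - 1 and p[hi + 1] >= half:
            hi += 1
    score = float(p[lo:hi + 1].sum() / total)
    return SpectrumResult(frequencies=spectrum.frequencies,
                          power=spectrum.power, score=score,
                          peak_interval=(float(spectrum.frequencies[lo]),
                                         float(spectrum.frequencies[hi])),
                          signal_variance=spectrum.signal_variance)


def one_peakness_score(spikes: SpikeTrain, series: CumulativeDistanceSeries,
                       bin_width: float = PSD_BIN,
                       rule: str = "local-min") -> float:
    """Convenience: one-peakness of a cell's path-integrated firing."""
    spec = psd(profile_for_psd(spikes, series, bin_width))
    return one_peakness(spec, rule).score


def idealized_lattice(track_field_distance: float,
                      orientation_deg: float = 0.0,
                      ratio: float = TRACK_ARENA_SPACING_RATIO,
                      field_width_2d: Optional[float] = None):
    """Idealized 2D lattice for a cell without an arena recording.

    The lattice spacing is the track field distance divided by the
    track-to-arena spacing ratio (1.85 on average across cells); the 2D
    field width defaults to spacing/6.
    """
    from .synth import GroundTruth
    if track_field_distance <= 0:
        raise ParameterError("field distance must be positive")
    spacing = track_field_distance / ratio
    return GroundTruth(coding_model="slice2d",
                       lattice_spacing=spacing,
                       orientation_deg=orientation_deg,
                       phase=(0.0, 0.0),
                       field_width_2d=field_width_2d or spacing / 6.0)


def fake_track_null(lattice, traj: Trajectory,
                    series: CumulativeDistanceSeries,
                    n_shifts: Tuple[int, int] = (10, 10),
                    seed: int = 0, bin_width: float = PSD_BIN,
                    percentile: float = 95.0,
                    rule: str = "local-min",
                    n_spikes: Optional[int] = None) -> SliceNull:
    """One-peakness null from sliding the real path over the 2D lattice.

    For every phase shift on an ``n_shifts`` grid covering one lattice
    unit cell, the lattice rate is sampled along the shifted path, a
    Poisson spike count is drawn per tracking sample, linearized onto
    the path-integrated axis and scored. Matching the sampling noise of
    an observed profile keeps observed and null scores on a common
    footing; ``n_spikes`` rescales each fake rate to the observed spike
    count (default: use the lattice rate as-is, in Hz).
    """
    from .synth import GroundTruth, lattice_rate

    if lattice is None:
        raise ParameterError("no lattice parameters available")
    if not isinstance(lattice, GroundTruth):
        lattice = GroundTruth.from_dict(dict(lattice))
    a = lattice.lattice_spacing
    phi = np.radians(lattice.orientation_deg)
    v1 = a * np.array([np.cos(phi), np.sin(phi)])
    v2 = a * np.array([np.cos(phi + np.pi / 3), np.sin(phi + np.pi / 3)])
    nu, nv = n_shifts
    if nu < 2 or nv < 2:
        raise ParameterError("need at least a 2x2 shift grid")
    rng = np.random.default_rng(seed)
    dt = traj.dt
    coord = series.signed
    lo = np.floor(coord.min() / bin_width) * bin_width
    hi = np.ceil(coord.max() / bin_width) * bin_width
    n = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n + 1)
    occ, _ = np.histogram(coord, bins=edges)
    occ = occ.astype(float) * dt
    scores = []
    for iu in range(nu):
        for iv in range(nv):
            shift = (iu + 0.5) / nu * v1 + (iv + 0.5) / nv * v2
            rate = lattice_rate(traj.x1 + shift[0], traj.y1 + shift[1],
                                lattice)
            expected = rate * dt
            tot = expected.sum()
            if n_spikes is not None and tot > 0:
                expected = expected * (n_spikes / tot)
            draws = rng.poisson(expected)
            cnt, _ = np.histogram(coord, bins=edges,
                                  weights=draws.astype(float))
            prof = LinearizedActivity(frame="path_integrated",
                                      bin_width=bin_width, edges=edges,
                                      counts=cnt, occupancy=occ)
            try:
                scores.append(one_peakness(psd(prof), rule).score)
            except InputError:
                scores.append(np.nan)
    return SliceNull(lattice=lattice.to_dict(), scores=np.asarray(scores),
                     percentile=percentile)


def slice_test(score: float, null: SliceNull) -> bool:
    """True when the observed one-peakness rejects the slice hypothesis."""
    if not np.isfinite(score):
        raise InputError("one-peakness score is not finite")
    return bool(score > null.threshold)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_spectrum(spectrum: SpectrumResult, path: str) -> None:
    """Spectrum as CSV with columns frequency,power."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frequency", "power"])
        for f, p in zip(spectrum.frequencies, spectrum.power):
            w.writerow([f"{f:.6g}", f"{p:.6g}"])


def write_null(null: SliceNull, path: str) -> None:
    """Null distribution as JSON."""
    with open(path, "w") as fh:
        json.dump({"lattice": null.lattice,
                   "percentile": null.percentile,
                   "threshold": null.threshold,
                   "scores": [float(s) for s in null.scores]},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
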