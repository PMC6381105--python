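"""Speed tuning, head-direction tuning, LFP theta and intrinsic theta.

Speed tuning averages firing rate in 2 cm/s speed bins; head-direction
tuning uses 6° bins with the Rayleigh vector length as directional
statistic. LFP theta is characterised by the mode of the instantaneous
frequency of the 4–12 Hz band-passed signal; intrinsic spike-train theta
is the analytic-signal peak frequency of the ±500 ms spike-time
autocorrelogram.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pingouin
from scipy import signal, stats

from .core import InputError, LFPSignal, ParameterError, SpikeTrain, Trajectory
from .linearize import InsufficientDataError

SPEED_BIN = 2.0           # cm/s
SPEED_MIN_OCCUPANCY = 1.0  # s per bin
HD_BIN = 6.0              # degrees
THETA_BAND = (4.0, 12.0)  # Hz
FREQ_HIST_BIN = 0.05      # Hz, for the instantaneous-frequency mode
AC_WINDOW = 0.5           # s, intrinsic autocorrelogram extent
AC_BIN = 0.001            # s
MIN_SPIKES_INTRINSIC = 100
THETA_INDEX_FLOOR = 5.0   # band-peak / band-median power: below → no peak


@dataclass
class SpeedTuning:
    """Firing rate versus running speed in 2 cm/s bins."""

    bin_centers: np.ndarray   # cm/s
    rates: np.ndarray         # Hz
    occupancy: np.ndarray     # s per kept bin
    r: float                  # Pearson r across bins
    slope: float              # Hz per cm/s
    intercept: float          # Hz

    @property
    def fisher_z(self) -> float:
        r = min(max(self.r, -0.999999), 0.999999)
        return float(np.arctanh(r))


@dataclass
class HDTuning:
    """Occupancy-normalised directional tuning in 6° bins."""

    bin_centers: np.ndarray   # deg, CCW from +x
    rates: np.ndarray         # Hz; NaN on unvisited bins
    occupancy: np.ndarray     # s
    vector_length: float      # Rayleigh vector length of the tuning curve
    pfd: float                # preferred firing direction, deg
    peak_rate: float          # Hz
    mean_rate: float          # Hz over the session


@dataclass
class ThetaResult:
    """LFP and intrinsic theta-band characterisation."""

    lfp_peak: float                   # Hz, mode of instantaneous frequency
    inst_freq: np.ndarray             # Hz at position samples
    speed_slope: float                # Hz per cm/s
    speed_r: float
    intrinsic_peak: float = float("nan")

    @property
    def in_band(self) -> bool:
        return bool(THETA_BAND[0] <= self.lfp_peak <= THETA_BAND[1])


# ---------------------------------------------------------------------------
# speed
# ---------------------------------------------------------------------------

def _per_sample_counts(spikes: SpikeTrain, traj: Trajectory) -> np.ndarray:
    edges = np.concatenate([traj.t, [traj.t[-1] + traj.dt]])
    counts, _ = np.histogram(spikes.times, bins=edges)
    return counts.astype(float)


def speed_tuning(spikes: SpikeTrain, traj: Trajectory,
                 bin_width: float = SPEED_BIN,
                 min_occupancy: float = SPEED_MIN_OCCUPANCY,
                 smooth_window: float = 0.5) -> SpeedTuning:
    """Firing rate per speed bin, with sample-level r and regression.

    The tuning curve averages rate in ``bin_width`` cm/s speed bins
    (bins occupied for less than ``min_occupancy`` seconds excluded).
    The Pearson r, slope and intercept correlate the instantaneous
    firing rate with running speed across tracking samples — both
    series smoothed with a ``smooth_window`` s boxcar.
    """
    if traj.duration < 60.0:
        raise InsufficientDataError("session shorter than 60 s")
    v = traj.speed(smooth_window)
    counts = _per_sample_counts(spikes, traj)
    inst = counts / traj.dt
    if smooth_window > 0:
        n = max(1, int(round(smooth_window / traj.dt)))
        inst = np.convolve(inst, np.ones(n) / n, mode="same")
    edges = bin_width * np.arange(int(np.ceil(v.max() / bin_width)) + 1)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    occ, _ = np.histogram(v, bins=edges)
    occ = occ.astype(float) * traj.dt
    cnt, _ = np.histogram(v, bins=edges, weights=counts)
    keep = occ >= min_occupancy
    if keep.sum() < 2:
        raise InputError("fewer than 2 speed bins with enough occupancy")
    centers = 0.5 * (edges[:-1] + edges[1:])[keep]
    rates = cnt[keep] / occ[keep]
    if np.std(v) == 0 or np.std(inst) == 0:
        raise InputError("speed–rate correlation undefined (constant input)")
    fit = stats.linregress(v, inst)
    return SpeedTuning(bin_centers=centers, rates=rates, occupancy=occ[keep],
                       r=float(fit.rvalue), slope=float(fit.slope),
                       intercept=float(fit.intercept))


def speed_cell_test(spikes: SpikeTrain, traj: Trajectory,
                    n_segments: int = 4, alpha: float = 0.05
                    ) -> Tuple[bool, float, float]:
    """Convention speed-cell test: segment-wise r, one-sample t on Fisher Z.

    The session is split into ``n_segments`` equal time segments, the
    speed–rate Pearson r computed in each, and the Fisher-Z values
    tested against zero. Returns (significant, mean r, p).
    """
    if n_segments < 3:
        raise ParameterError("need at least 3 segments")
    bounds = np.linspace(traj.t[0], traj.t[-1] + traj.dt, n_segments + 1)
    zs = []
    rs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        idx = (traj.t >= a) & (traj.t < b)
        if idx.sum() < 10:
            continue
        sub = Trajectory(t=traj.t[idx], x1=traj.x1[idx], y1=traj.y1[idx],
                         x2=traj.x2[idx] if traj.has_heading else None,
                         y2=traj.y2[idx] if traj.has_heading else None)
        sub_spk = SpikeTrain(times=spikes.times[(spikes.times >= a)
                                                & (spikes.times < b)],
                             unit_id=spikes.unit_id)
        try:
            st = speed_tuning(sub_spk, sub, min_occupancy=0.5)
        except (InputError, InsufficientDataError):
            continue
        rs.append(st.r)
        zs.append(st.fisher_z)
    if len(zs) < 3:
        raise InsufficientDataError("fewer than 3 usable segments")
    t_res = stats.ttest_1samp(zs, 0.0)
    return bool(t_res.pvalue < alpha), float(np.tanh(np.mean(zs))), \
        float(t_res.pvalue)


# ---------------------------------------------------------------------------
# head direction
# ---------------------------------------------------------------------------

def hd_tuning(spikes: SpikeTrain, traj: Trajectory,
              bin_width: float = HD_BIN) -> HDTuning:
    """Directional tuning: spikes per heading bin over time facing it."""
    heading = traj.heading()          # deg, raises if no second marker
    counts = _per_sample_counts(spikes, traj)
    nbins = int(round(360.0 / bin_width))
    edges = bin_width * np.arange(nbins + 1)
    occ, _ = np.histogram(heading, bins=edges)
    occ = occ.astype(float) * traj.dt
    cnt, _ = np.histogram(heading, bins=edges, weights=counts)
    if not (occ > 0).any():
        raise InputError("no occupied direction bins")
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = cnt / occ
    rates[occ == 0] = np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = np.isfinite(rates)
    total = np.nansum(rates)
    if total <= 0:
        raise InputError("cell fired no spikes in any occupied direction")
    ang = np.radians(centers[ok])
    w = rates[ok]
    vec = np.sum(w * np.exp(1j * ang)) / np.sum(w)
    j = int(np.nanargmax(rates))
    return HDTuning(bin_centers=centers, rates=rates, occupancy=occ,
                    vector_length=float(np.abs(vec)),
                    pfd=float(centers[j]),
                    peak_rate=float(rates[j]),
                    mean_rate=float(spikes.n_spikes / traj.duration))


def hd_shuffle_threshold(cells: Sequence[Tuple[Trajectory, SpikeTrain]],
                         n_per_cell: int = 400, percentile: float = 99.0,
                         seed: int = 0, min_shift: float = 20.0
                         ) -> Tuple[float, np.ndarray]:
    """Rayleigh vector-length threshold from time-rotated spike trains.

    Spike times are circularly rotated by random offsets in
    [min_shift, duration − min_shift]; vector lengths from all rotations
    of all cells are pooled and the stated percentile returned.
    """
    rng = np.random.default_rng(seed)
    vls = []
    for traj, spikes in cells:
        T = traj.duration
        if T < 2 * min_shift:
            continue
        for _ in range(n_per_cell):
            shift = rng.uniform(min_shift, T - min_shift)
            rolled = SpikeTrain(times=np.mod(spikes.times + shift, T),
                                unit_id=spikes.unit_id)
            try:
                vls.append(hd_tuning(rolled, traj).vector_length)
            except InputError:
                continue
    vls = np.asarray(vls)
    if vls.size == 0:
        raise InsufficientDataError("no usable rotations")
    return float(np.percentile(vls, percentile)), vls


def is_hd_cell(tuning: HDTuning, threshold: float = 0.24,
               min_rate: float = 1.0) -> bool:
    """HD-cell criterion: vector length ≥ threshold and rate > min_rate."""
    return bool(tuning.vector_length >= threshold
                and tuning.mean_rate > min_rate)


def pfd_stability(pairs: Sequence[Tuple[HDTuning, HDTuning]]
                  ) -> Tuple[np.ndarray, float, float]:
    """Circular PFD differences across environments, V-test toward 0°.

    Returns (differences in degrees within ±180°, V statistic, p-value).
    """
    if len(pairs) < 3:
        raise InsufficientDataError("fewer than 3 paired tunings")
    diffs = np.array([(b.pfd - a.pfd + 180.0) % 360.0 - 180.0
                      for a, b in pairs])
    v, p = pingouin.circ_vtest(np.radians(diffs), dir=0.0)
    return diffs, float(v), float(p)


# ---------------------------------------------------------------------------
# theta
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, fs: float,
              band: Tuple[float, float] = THETA_BAND) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def lfp_theta(lfp: LFPSignal, traj: Trajectory,
              band: Tuple[float, float] = THETA_BAND,
              hist_bin: float = FREQ_HIST_BIN) -> ThetaResult:
    """Theta peak and frequency–speed relation of an LFP trace.

    The trace is band-passed (zero-phase), the analytic-signal
    instantaneous frequency extracted, downsampled to the position
    sampling rate, and the peak defined as the mode of its histogram in
    ``hist_bin`` Hz bins. The slope is the linear regression of
    instantaneous frequency on running speed.
    """
    if lfp.duration < 10.0:
        raise InsufficientDataError("LFP shorter than 10 s")
    if np.std(lfp.values) == 0:
        raise InputError("flat LFP signal")
    fs = lfp.sample_rate
    filt = _bandpass(lfp.values, fs, band)
    analytic = signal.hilbert(filt)
    phase = np.unwrap(np.angle(analytic))
    inst = np.gradient(phase) * fs / (2.0 * np.pi)
    # downsample to the position sampling rate
    inst_pos = np.interp(traj.t, lfp.t, inst)
    lo = np.floor(inst_pos.min() / hist_bin) * hist_bin
    nbin = max(1, int(np.ceil((inst_pos.max() - lo) / hist_bin)))
    hist, hedges = np.histogram(inst_pos, bins=lo + hist_bin * np.arange(nbin + 1))
    peak = float(0.5 * (hedges[np.argmax(hist)] + hedges[np.argmax(hist) + 1]))
    v = traj.speed()
    if np.std(v) > 0:
        fit = stats.linregress(v, inst_pos)
        slope, r = float(fit.slope), float(fit.rvalue)
    else:
        slope, r = float("nan"), float("nan")
    return ThetaResult(lfp_peak=peak, inst_freq=inst_pos,
                       speed_slope=slope, speed_r=r)


def spike_autocorrelogram(spikes: SpikeTrain, window: float = AC_WINDOW,
                          bin_width: float = AC_BIN
                          ) -> Tuple[np.ndarray, np.ndarray]:
    """Spike-time autocorrelogram at positive lags (counts per bin)."""
    t = spikes.times
    nbins = int(round(window / bin_width))
    counts = np.zeros(nbins)
    hi = np.searchsorted(t, t + window, side="left")
    for i, h in enumerate(hi):
        lags = t[i + 1:h] - t[i]
        if lags.size:
            idx = np.minimum((lags / bin_width).astype(int), nbins - 1)
            np.add.at(counts, idx, 1.0)
    lags = bin_width * (np.arange(nbins) + 0.5)
    return lags, counts


def intrinsic_theta(spikes: SpikeTrain, window: float = AC_WINDOW,
                    bin_width: float = AC_BIN,
                    band: Tuple[float, float] = THETA_BAND,
                    index_floor: float = THETA_INDEX_FLOOR
                    ) -> Tuple[float, float]:
    """Intrinsic theta frequency of a spike train; (Hz, theta index).

    The ±500 ms spike-time autocorrelogram (1 ms bins) is mean-
    subtracted and band-passed; the frequency is the envelope-weighted
    mean instantaneous frequency of its analytic signal. The theta
    index is the band-peak over band-median periodogram power; below
    ``index_floor`` the cell is flagged as having no theta peak (NaN).
    Requires at least 100 spikes.
    """
    if spikes.n_spikes < MIN_SPIKES_INTRINSIC:
        raise InsufficientDataError(
            f"{spikes.n_spikes} spikes; intrinsic theta needs "
            f">= {MIN_SPIKES_INTRINSIC}")
    _, ac = spike_autocorrelogram(spikes, window, bin_width)
    fs = 1.0 / bin_width
    x = ac - ac.mean()
    if np.std(x) == 0:
        return float("nan"), 0.0
    freqs, power = signal.periodogram(x, fs=fs, detrend="constant")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    wide = (freqs >= band[0]) & (freqs <= 50.0)
    band_peak = power[in_band].max() if in_band.any() else 0.0
    ref = np.median(power[wide]) if wide.any() else 0.0
    theta_index = float(band_peak / ref) if ref > 0 else 0.0
    if theta_index < index_floor:
        return float("nan"), theta_index
    # mirror to a symmetric ±window sequence so the analytic signal is
    # not edge-biased at lag zero
    xs = np.concatenate([x[::-1], [x[0]], x])
    filt = _bandpass(xs, fs, band)
    analytic = signal.hilbert(filt)
    env = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    inst = np.gradient(phase) * fs / (2.0 * np.pi)
    trim = min(100, xs.size // 8)
    sl = slice(trim, xs.size - trim)
    ok = (inst[sl] >= band[0]) & (inst[sl] <= band[1])
    if not ok.any():
        return float("nan"), theta_index
    w = env[sl][ok] ** 2
    return float(np.average(inst[sl][ok], weights=w)), theta_index


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_tuning_csv(tuning, path: str) -> None:
    """Speed or HD tuning curve as CSV (bin_center, rate, occupancy)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bin_center", "rate", "occupancy"])
        for c, r, o in zip(tuning.bin_centers, tuning.rates, tuning.occupancy):
            w.writerow([f"{c:.6g}", f"{r:.6g}", f"{o:.6g}"])
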