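"""Coding-scheme inference for track sessions.

Distinguishes four candidate schemes for grid-cell firing on a circular
track: allocentric position (fields fixed in track coordinates across
laps), path-integrated distance (fields at constant signed-distance
intervals, so they precess lap to lap by C mod Δ), travelled distance,
and elapsed time. Regularity in each frame is scored as the mean of the
first two peaks of the linearized firing autocorrelation and compared to
a jitter-surrogate null; the allocentric alternative is scored by the
lap-pairwise spatial correlation, with and without the path-integration
shift correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.linalg import toeplitz as _toeplitz
from scipy.signal import fftconvolve, find_peaks

from .core import GridtrackError, ParameterError, SpikeTrain
from .linearize import (
    DEFAULT_BIN,
    FRAMES,
    CumulativeDistanceSeries,
    InsufficientDataError,
    LapMatrix,
    LinearizedActivity,
    lap_position_matrix,
    linearize_activity,
    segment_laps,
)

MIN_OVERLAP_1D = 20     # bins of mutual occupancy per autocorrelation lag
MIN_PAIR_OVERLAP = 10   # bins for a lap-pair correlation
PEAK_FLOOR = 0.1        # fallback peak height for the field distance


# ---------------------------------------------------------------------------
# Fisher Z
# ---------------------------------------------------------------------------

def fisher_z(r: float) -> float:
    """Fisher Z-transform; |r| = 1 is clipped to 0.999999."""
    if abs(r) > 1 + 1e-9:
        raise ParameterError(f"|r| > 1: {r}")
    r = float(np.clip(r, -0.999999, 0.999999))
    return float(np.arctanh(r))


def fisher_z_inverse(z: float) -> float:
    return float(np.tanh(z))


def mean_correlation(rs) -> float:
    """Fisher-Z-averaged mean of correlation coefficients."""
    rs = [r for r in rs if np.isfinite(r)]
    if not rs:
        return float("nan")
    return fisher_z_inverse(float(np.mean([fisher_z(r) for r in rs])))


# ---------------------------------------------------------------------------
# 1D masked Pearson autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class AutocorrSequence1D:
    """Pearson autocorrelation of a linearized firing profile."""

    lags: np.ndarray           # physical units (cm or s), lag 0 first
    values: np.ndarray         # NaN where overlap insufficient
    bin_width: float
    peak_lags: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def first_peak_lag(self) -> float:
        return float(self.peak_lags[0]) if self.peak_lags.size else float("nan")

    @property
    def mean_first_two(self) -> float:
        """Mean of the first two peak values (NaN with <2 peaks)."""
        if self.peak_values.size < 2:
            return float("nan")
        return float(self.peak_values[:2].mean())

    def toeplitz(self, extent: float = 500.0) -> np.ndarray:
        """Toeplitz rendering of the autocorrelation (default 500 cm)."""
        n = min(int(round(extent / self.bin_width)), self.values.size)
        return _toeplitz(np.nan_to_num(self.values[:n], nan=0.0))


def _masked_pearson_lags(a: np.ndarray, ma: np.ndarray,
                         b: np.ndarray, mb: np.ndarray,
                         min_overlap: int = MIN_OVERLAP_1D) -> np.ndarray:
    """Pearson correlation of two masked 1D signals at every lag.

    Returns the full lag axis -(L-1)..(L-1) (length 2L-1).
    """
    za = np.where(ma, a, 0.0)
    zb = np.where(mb, b, 0.0)
    fa = ma.astype(float)
    fb = mb.astype(float)

    def cc(u, v):
        return fftconvolve(u, v[::-1], mode="full")

    n = np.round(cc(fa, fb))
    sxy = cc(za, zb)
    sx = cc(za, fb)
    sy = cc(fa, zb)
    sxx = cc(za * za, fb)
    syy = cc(fa, zb * zb)
    with np.errstate(divide="ignore", invalid="ignore"):
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        r = (n * sxy - sx * sy) / np.sqrt(vx * vy)
    r[(n < min_overlap) | (vx <= 1e-9) | (vy <= 1e-9)] = np.nan
    return np.clip(r, -1.0, 1.0)


def _extract_peaks(values: np.ndarray, min_separation: int = 2
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Local maxima above zero, at least ``min_separation`` bins apart."""
    filled = np.nan_to_num(values, nan=-np.inf)
    idx, _ = find_peaks(filled, height=0.0, distance=min_separation)
    return idx, values[idx]


def autocorrelation_1d(profile: LinearizedActivity,
                       min_overlap: int = MIN_OVERLAP_1D
                       ) -> AutocorrSequence1D:
    """Spatial (or temporal) autocorrelation of a linearized profile.

    Correlations are computed per lag over mutually occupied bins only;
    peaks are local maxima above zero separated by at least two bins.
    """
    rate = profile.rate
    occ = profile.occupied
    finite = rate[occ]
    if finite.size < min_overlap:
        raise InsufficientDataError("profile too short for autocorrelation")
    if np.std(finite) == 0:
        raise GridtrackError("constant profile: correlation undefined")
    vals = np.nan_to_num(rate, nan=0.0)
    full = _masked_pearson_lags(vals, occ, vals, occ, min_overlap)
    L = rate.size
    pos = full[L - 1:]                       # lags 0..L-1
    lags = profile.bin_width * np.arange(L)
    pidx, pvals = _extract_peaks(pos)
    keep = pidx > 0
    return AutocorrSequence1D(lags=lags, values=pos,
                              bin_width=profile.bin_width,
                              peak_lags=lags[pidx[keep]],
                              peak_values=pvals[keep])


def crosscorrelation_1d(a: LinearizedActivity, b: LinearizedActivity
                        ) -> AutocorrSequence1D:
    """Pearson cross-correlation of two profiles on a common grid."""
    if a.bin_width != b.bin_width:
        raise ParameterError("profiles have different bin widths")
    lo = min(a.edges[0], b.edges[0])
    hi = max(a.edges[-1], b.edges[-1])
    n = int(round((hi - lo) / a.bin_width))

    def embed(p):
        out = np.zeros(n)
        mask = np.zeros(n, bool)
        i0 = int(round((p.edges[0] - lo) / p.bin_width))
        out[i0:i0 + p.counts.size] = np.nan_to_num(p.rate, nan=0.0)
        mask[i0:i0 + p.counts.size] = p.occupied
        return out, mask

    va, mask_a = embed(a)
    vb, mask_b = embed(b)
    full = _masked_pearson_lags(va, mask_a, vb, mask_b)
    lags = a.bin_width * np.arange(-(n - 1), n)
    pidx, pvals = _extract_peaks(full)
    return AutocorrSequence1D(lags=lags, values=full, bin_width=a.bin_width,
                              peak_lags=lags[pidx], peak_values=pvals)


def field_distance_from_autocorr(acorr: AutocorrSequence1D,
                                 threshold: float = PEAK_FLOOR) -> float:
    """Distance between firing fields: lag of the first significant peak.

    The first local maximum above ``threshold`` is used; if none exceeds
    it, the first above 0.1; NaN when no peak qualifies.
    """
    for thr in (threshold, PEAK_FLOOR):
        above = acorr.peak_values >= thr
        if above.any():
            return float(acorr.peak_lags[np.argmax(above)])
    return float("nan")


# ---------------------------------------------------------------------------
# lap correlations (allocentric vs path-integration corrected)
# ---------------------------------------------------------------------------

def _pairwise_mean_r(rows: np.ndarray,
                     min_overlap: int = MIN_PAIR_OVERLAP) -> float:
    """Fisher-averaged Pearson correlation over all row pairs."""
    L = rows.shape[0]
    rs = []
    for i in range(L):
        for j in range(i + 1, L):
            both = np.isfinite(rows[i]) & np.isfinite(rows[j])
            if both.sum() < min_overlap:
                continue
            a, b = rows[i][both], rows[j][both]
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    return mean_correlation(rs)


def allocentric_correlation(lapmat: LapMatrix) -> float:
    """Mean lap-pairwise spatial correlation (no shift): allocentric score."""
    if lapmat.n_laps < 2:
        raise InsufficientDataError("need at least two laps")
    return _pairwise_mean_r(lapmat.rates)


def _fractional_roll(row: np.ndarray, shift_bins: float) -> np.ndarray:
    """Circular shift by a fractional number of bins (linear interpolation)."""
    n = row.size
    s = shift_bins % n
    i0 = int(np.floor(s))
    frac = s - i0
    if frac == 0.0:
        return np.roll(row, i0)
    return (1.0 - frac) * np.roll(row, i0) + frac * np.roll(row, i0 + 1)


@dataclass
class CorrectedCorrelation:
    """Lap correlation after the path-integrated distance correction."""

    mean_r: float
    residual: float          # C mod field_distance (cm)
    fell_back: bool = False  # field distance unusable; allocentric value


def _lap_residual(C: float, field_distance: float) -> float:
    """C mod field_distance, robust to exact divisors.

    When the field distance divides the circumference exactly (e.g. C/3),
    floating point can make ``np.mod`` return the divisor instead of 0;
    flooring the quotient with a small tolerance gives a residual of 0 so
    the correction is the identity it should be.
    """
    q = C / field_distance
    return float((q - np.floor(q + 1e-9)) * field_distance)


def shifted_lap_matrix(lapmat: LapMatrix, field_distance: float) -> np.ndarray:
    """Lap rows re-aligned under the path-integration hypothesis.

    A Δ-periodic pattern in signed distance appears in lap k at track
    positions shifted by -k·(C mod Δ) relative to lap 0, independent of
    running direction (negative lap indices carry the sign); adding
    +k·(C mod Δ) to each lap's positions re-aligns the pattern.
    """
    residual = _lap_residual(lapmat.circumference, field_distance)
    shift_bins = residual / lapmat.bin_width
    k0 = lapmat.lap_ids[0]
    return np.array([
        _fractional_roll(lapmat.rates[i], (k - k0) * shift_bins)
        for i, k in enumerate(lapmat.lap_ids)
    ])


def path_integrated_correlation(lapmat: LapMatrix,
                                field_distance: float) -> CorrectedCorrelation:
    """Mean lap correlation after shifting laps by C mod field distance."""
    if not np.isfinite(field_distance) or field_distance <= lapmat.bin_width:
        return CorrectedCorrelation(mean_r=allocentric_correlation(lapmat),
                                    residual=float("nan"), fell_back=True)
    rows = shifted_lap_matrix(lapmat, field_distance)
    return CorrectedCorrelation(
        mean_r=_pairwise_mean_r(rows),
        residual=_lap_residual(lapmat.circumference, field_distance))


@dataclass
class SplitHalfResult:
    field_distance: float
    corrected_r: float
    allocentric_r: float


def split_half_control(spikes: SpikeTrain,
                       series: CumulativeDistanceSeries,
                       C: float, nbins: int = 47,
                       bin_width: float = 10.0) -> SplitHalfResult:
    """Cross-validated correction: distance from the first half of the
    laps, correction evaluated on the second half. Requires >= 4 laps."""
    lap = segment_laps(series, C)
    ids = np.unique(lap)
    if ids.size < 4:
        raise InsufficientDataError("fewer than 4 laps: control skipped")
    n_first = int(np.ceil(ids.size / 2))
    first_ids = set(ids[:n_first].tolist())
    mask_first = np.isin(lap, list(first_ids))
    prof = linearize_activity(spikes, series, "path_integrated", bin_width,
                              sample_mask=mask_first)
    dist = field_distance_from_autocorr(autocorrelation_1d(prof))
    full = lap_position_matrix(spikes, series, C, nbins)
    second = ~np.isin(full.lap_ids, list(first_ids))
    sub = LapMatrix(rates=full.rates[second], occupancy=full.occupancy[second],
                    counts=full.counts[second], lap_ids=full.lap_ids[second],
                    circumference=C)
    return SplitHalfResult(
        field_distance=dist,
        corrected_r=path_integrated_correlation(sub, dist).mean_r,
        allocentric_r=allocentric_correlation(sub))


# ---------------------------------------------------------------------------
# jitter surrogates
# ---------------------------------------------------------------------------

@dataclass
class JitterNull:
    """Null distribution of mean-first-two-peak values for one frame."""

    frame: str
    n: int
    percentile: float
    stats: np.ndarray
    seed: int

    @property
    def threshold(self) -> float:
        return float(np.nanpercentile(self.stats, self.percentile))


def jitter_statistics(spikes: SpikeTrain,
                      series: CumulativeDistanceSeries,
                      frames=FRAMES, n: int = 400, seed: int = 0,
                      max_jitter: float = 0.5, mode: str = "isi"
                      ) -> Dict[str, np.ndarray]:
    """Mean-first-two-peak statistics of jitter-surrogate spike trains.

    The noise magnitude ranges from one fifth of the smallest inter-spike
    interval up to ``max_jitter`` (0.5 s). Two noise laws are available:

    ``"isi"`` (default): every inter-spike interval is perturbed by a
    random-sign magnitude drawn uniformly from that range and the train
    is rebuilt by cumulative summation. Displacements accumulate along
    the train, which destroys the long-range regularity the statistic
    measures while preserving rate and local spike structure — jittered
    statistics of even strongly periodic cells collapse to a fraction of
    the observed value, which is what makes a percentile threshold of the
    null distribution discriminative.

    ``"spike"``: a single scale is drawn per permutation and each spike
    is displaced independently within ±scale. Displacements stay below
    half a bin of the linearized profiles, so this mode barely perturbs
    the statistic; it is kept for comparison only.
    """
    if n < 1:
        raise ParameterError("need at least one permutation")
    if spikes.n_spikes < 2:
        raise InsufficientDataError("need at least two spikes to jitter")
    if mode not in ("isi", "spike"):
        raise ParameterError(f"unknown jitter mode {mode!r}")
    rng = np.random.default_rng(seed)
    isi = np.diff(spikes.times)
    lo = max(float(isi[isi > 0].min()) / 5.0, 1e-6) if np.any(isi > 0) else 1e-6
    lo = min(lo, max_jitter)
    t0, t1 = series.t[0], series.t[-1]
    # occupancy and bin edges are jitter-invariant: precompute per frame
    pre = {}
    for fr in frames:
        p = linearize_activity(spikes, series, fr)
        pre[fr] = p
    out = {fr: np.full(n, np.nan) for fr in frames}
    for k in range(n):
        if mode == "isi":
            mag = rng.uniform(lo, max_jitter, isi.size)
            sign = rng.choice([-1.0, 1.0], isi.size)
            new_isi = np.clip(isi + sign * mag, 0.0, None)
            jit = spikes.times[0] + np.concatenate(([0.0],
                                                    np.cumsum(new_isi)))
        else:
            scale = rng.uniform(lo, max_jitter)
            jit = np.sort(spikes.times
                          + rng.uniform(-scale, scale, spikes.n_spikes))
        # drop spikes displaced outside the session: clipping them onto
        # the boundary would pile them into one bin and bias the
        # statistic down
        jit = jit[(jit >= t0) & (jit <= t1)]
        for fr in frames:
            p = pre[fr]
            coord = series.frame_coordinate(fr)
            sc = np.interp(jit, series.t, coord)
            counts, _ = np.histogram(sc, bins=p.edges)
            prof = LinearizedActivity(frame=fr, bin_width=p.bin_width,
                                      edges=p.edges,
                                      counts=counts.astype(float),
                                      occupancy=p.occupancy)
            try:
                out[fr][k] = autocorrelation_1d(prof).mean_first_two
            except GridtrackError:
                pass
    return out


def jitter_null(spikes: SpikeTrain, series: CumulativeDistanceSeries,
                frame: str, n: int = 400, percentile: float = 99.0,
                seed: int = 0, mode: str = "isi") -> JitterNull:
    """Per-cell jitter null distribution and threshold for one frame."""
    stats = jitter_statistics(spikes, series, frames=(frame,), n=n,
                              seed=seed, mode=mode)[frame]
    return JitterNull(frame=frame, n=n, percentile=percentile, stats=stats,
                      seed=seed)


# ---------------------------------------------------------------------------
# per-cell classification
# ---------------------------------------------------------------------------

def _nan_pearson_rows(A: np.ndarray, B: np.ndarray,
                      min_overlap: int = MIN_PAIR_OVERLAP) -> np.ndarray:
    """Row-wise Pearson correlation of two (P, B) arrays with NaNs."""
    m = np.isfinite(A) & np.isfinite(B)
    a = np.where(m, A, 0.0)
    b = np.where(m, B, 0.0)
    n = m.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sx = a.sum(1)
        sy = b.sum(1)
        vx = n * (a * a).sum(1) - sx * sx
        vy = n * (b * b).sum(1) - sy * sy
        r = (n * (a * b).sum(1) - sx * sy) / np.sqrt(vx * vy)
    r[(n < min_overlap) | (vx <= 1e-9) | (vy <= 1e-9)] = np.nan
    return r


def allocentric_permutation_p(lapmat: LapMatrix, n_perm: int = 1000,
                              seed: int = 0) -> Tuple[float, float]:
    """Per-cell allocentric significance by lap-row rotation.

    Each permutation circularly rotates every lap row by an independent
    random number of bins; p is the fraction of permuted mean correlations
    at least as large as the observed one.
    """
    obs = allocentric_correlation(lapmat)
    if not np.isfinite(obs):
        return obs, float("nan")
    rng = np.random.default_rng(seed)
    L, B = lapmat.rates.shape
    shifts = rng.integers(0, B, size=(n_perm, L))
    cols = (np.arange(B)[None, None, :] - shifts[:, :, None]) % B
    rolled = lapmat.rates[np.arange(L)[None, :, None], cols]   # (P, L, B)
    zsum = np.zeros(n_perm)
    zcount = np.zeros(n_perm)
    for i in range(L):
        for j in range(i + 1, L):
            r = _nan_pearson_rows(rolled[:, i, :], rolled[:, j, :])
            ok = np.isfinite(r)
            zsum[ok] += np.arctanh(np.clip(r[ok], -0.999999, 0.999999))
            zcount[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        perm_r = np.tanh(zsum / zcount)
    perm_r = perm_r[np.isfinite(perm_r)]
    if perm_r.size == 0:
        return obs, float("nan")
    p = float((np.sum(perm_r >= obs) + 1) / (perm_r.size + 1))
    return obs, p


@dataclass
class CodingClassification:
    """Per-cell coding flags with all intermediate scores."""

    unit_id: str
    stats: Dict[str, float]          # frame -> mean of first two peaks
    thresholds: Dict[str, float]
    flags: Dict[str, bool]
    field_distance: float            # cm, from the path-integrated autocorr
    allocentric_r: float
    allocentric_p: float
    allocentric_flag: bool
    corrected_r: float
    degenerate: bool = False

    @property
    def label(self) -> str:
        """Single assigned label for confusion-matrix summaries.

        A track-anchored (allocentric) cell is also periodic in signed
        distance, so the allocentric label takes precedence when the
        rotation test fires and the uncorrected lap correlation is not
        beaten by the path-integration correction.
        """
        if self.degenerate:
            return "none"
        if self.allocentric_flag and (
                not np.isfinite(self.corrected_r)
                or self.allocentric_r >= self.corrected_r):
            return "allocentric"
        flagged = [f for f in FRAMES if self.flags.get(f)]
        if flagged:
            return max(flagged,
                       key=lambda f: self.stats[f] - self.thresholds[f])
        if self.allocentric_flag:
            return "allocentric"
        return "none"


def classify_cell(spikes: SpikeTrain, series: CumulativeDistanceSeries,
                  thresholds: Dict[str, float], C: float,
                  nbins: int = 47, alloc_n_perm: int = 1000,
                  alloc_alpha: float = 0.05, seed: int = 0,
                  unit_id: str = "unit0") -> CodingClassification:
    """Classify one track cell against pre-computed jitter thresholds.

    A frame is flagged when the cell's autocorrelation has at least two
    peaks and their mean value reaches the frame's threshold. The
    allocentric flag comes from a per-cell lap-rotation permutation test.
    """
    for fr in FRAMES:
        if fr not in thresholds:
            raise ParameterError(f"missing jitter threshold for {fr!r}")
    if spikes.n_spikes < 5:
        return CodingClassification(
            unit_id=unit_id, stats={f: float("nan") for f in FRAMES},
            thresholds=dict(thresholds), flags={f: False for f in FRAMES},
            field_distance=float("nan"), allocentric_r=float("nan"),
            allocentric_p=float("nan"), allocentric_flag=False,
            corrected_r=float("nan"), degenerate=True)
    stats = {}
    flags = {}
    pi_acorr = None
    for fr in FRAMES:
        prof = linearize_activity(spikes, series, fr)
        try:
            ac = autocorrelation_1d(prof)
            stats[fr] = ac.mean_first_two
        except GridtrackError:
            ac = None
            stats[fr] = float("nan")
        if fr == "path_integrated":
            pi_acorr = ac
        flags[fr] = bool(np.isfinite(stats[fr])
                         and stats[fr] >= thresholds[fr])
    if pi_acorr is not None:
        dist = field_distance_from_autocorr(pi_acorr,
                                            thresholds["path_integrated"])
    else:
        dist = float("nan")
    try:
        lapmat = lap_position_matrix(spikes, series, C, nbins)
        alloc_r, alloc_p = allocentric_permutation_p(lapmat, alloc_n_perm,
                                                     seed)
        corrected = path_integrated_correlation(lapmat, dist).mean_r
    except InsufficientDataError:
        alloc_r = alloc_p = corrected = float("nan")
    alloc_flag = bool(np.isfinite(alloc_p) and alloc_p < alloc_alpha)
    return CodingClassification(
        unit_id=unit_id, stats=stats, thresholds=dict(thresholds),
        flags=flags, field_distance=dist, allocentric_r=alloc_r,
        allocentric_p=alloc_p, allocentric_flag=alloc_flag,
        corrected_r=corrected)
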