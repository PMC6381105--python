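"""2D firing-rate maps, spatial autocorrelograms and grid metrics.

Rate maps use 2.5 cm square bins and a Gaussian quotient-kernel estimator
(spike kernel sum over occupancy kernel integral, smoothing factor
h = 2 bins = 5 cm). Autocorrelograms are Pearson correlations per spatial
lag computed only over mutually visited bins, with a minimum-overlap
guard. The gridness score correlates the annular region around the six
inner peaks with itself rotated by 60°/120° versus 30°/90°/150°.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .core import InputError, ParameterError, SpikeTrain, Trajectory
from .linearize import InsufficientDataError, LinearizedActivity

DEFAULT_BIN = 2.5            # cm
DEFAULT_SMOOTH = 2 * 2.5     # cm, Gaussian smoothing factor h
MIN_OVERLAP = 20             # bins per lag in correlograms
PEAK_FLOOR = 0.1             # autocorrelogram local maxima below this ignored
CENTRAL_FLOOR = 0.2          # extent of the central peak


@dataclass
class SmoothingSpec:
    """Gaussian smoothing kernel specification for rate maps."""

    h: float = DEFAULT_SMOOTH   # cm
    bin: float = DEFAULT_BIN    # cm

    def __post_init__(self) -> None:
        if self.h <= 0 or self.bin <= 0:
            raise ParameterError("h and bin must be positive")


@dataclass
class RateMap2D:
    """Occupancy-normalised firing-rate grid (Hz per bin)."""

    rate: np.ndarray          # NaN on unvisited bins
    occupancy: np.ndarray     # raw (unsmoothed) seconds per bin
    mask: np.ndarray          # visited bins
    bin: float
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rate)) if self.mask.any() else 0.0


@dataclass
class Autocorrelogram2D:
    """Pearson correlation per spatial lag, with overlap counts."""

    values: np.ndarray        # NaN where overlap insufficient
    n_overlap: np.ndarray
    bin: float

    @property
    def center(self) -> Tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)

    def lag_distance(self) -> np.ndarray:
        """Distance of each lag bin from zero lag, in cm."""
        cy, cx = self.center
        yy, xx = np.mgrid[0:self.values.shape[0], 0:self.values.shape[1]]
        return np.hypot(yy - cy, xx - cx) * self.bin


@dataclass
class Field:
    """One firing field: member bins, peak rate, centroid."""

    indices: np.ndarray       # flat bin indices (2D) or bin indices (1D)
    peak_rate: float
    centroid: np.ndarray      # (x, y) cm for 2D maps, coordinate for 1D


@dataclass
class FieldSet:
    fields: List[Field]

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    @property
    def peak_rate_sd(self) -> float:
        if not self.fields:
            return float("nan")
        return float(np.std([f.peak_rate for f in self.fields]))


def compute_rate_map(traj: Trajectory, spikes: SpikeTrain,
                     spec: Optional[SmoothingSpec] = None,
                     extent: Optional[float] = None) -> RateMap2D:
    """Quotient-kernel rate map: smoothed spikes over smoothed occupancy."""
    spec = spec or SmoothingSpec()
    if traj.n_samples < 2:
        raise InputError("empty trajectory")
    if extent is None:
        extent = float(np.ceil(max(np.abs(traj.x1).max(),
                                   np.abs(traj.y1).max()) / spec.bin) * spec.bin)
    n = int(round(2 * extent / spec.bin))
    edges = -extent + spec.bin * np.arange(n + 1)
    occ, _, _ = np.histogram2d(traj.y1, traj.x1, bins=(edges, edges))
    occ *= traj.dt
    sx = np.interp(spikes.times, traj.t, traj.x1)
    sy = np.interp(spikes.times, traj.t, traj.y1)
    cnt, _, _ = np.histogram2d(sy, sx, bins=(edges, edges))
    sigma = spec.h / spec.bin
    num = ndimage.gaussian_filter(cnt, sigma)
    den = ndimage.gaussian_filter(occ, sigma)
    mask = occ > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(den > 1e-12, num / den, 0.0)
    rate[~mask] = np.nan
    return RateMap2D(rate=rate, occupancy=occ, mask=mask, bin=spec.bin,
                     x_edges=edges, y_edges=edges)


def rate_map_from_weights(traj: Trajectory, weights: np.ndarray,
                          spec: Optional[SmoothingSpec] = None,
                          extent: Optional[float] = None) -> RateMap2D:
    """Rate map of a per-sample expected spike count (model intensity).

    Same estimator as :func:`compute_rate_map`, with the spike-count
    histogram replaced by the sum of ``weights`` per bin.
    """
    spec = spec or SmoothingSpec()
    weights = np.asarray(weights, dtype=float)
    if weights.shape != traj.t.shape:
        raise InputError("weights must have one value per tracking sample")
    if extent is None:
        extent = float(np.ceil(max(np.abs(traj.x1).max(),
                                   np.abs(traj.y1).max()) / spec.bin) * spec.bin)
    n = int(round(2 * extent / spec.bin))
    edges = -extent + spec.bin * np.arange(n + 1)
    occ, _, _ = np.histogram2d(traj.y1, traj.x1, bins=(edges, edges))
    occ *= traj.dt
    cnt, _, _ = np.histogram2d(traj.y1, traj.x1, bins=(edges, edges),
                               weights=weights)
    sigma = spec.h / spec.bin
    num = ndimage.gaussian_filter(cnt, sigma)
    den = ndimage.gaussian_filter(occ, sigma)
    mask = occ > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(den > 1e-12, num / den, 0.0)
    rate[~mask] = np.nan
    return RateMap2D(rate=rate, occupancy=occ, mask=mask, bin=spec.bin,
                     x_edges=edges, y_edges=edges)


def _masked_crosscorr(a: np.ndarray, mask_a: np.ndarray,
                      b: np.ndarray, mask_b: np.ndarray,
                      min_overlap: int = MIN_OVERLAP
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of two masked grids at every spatial lag.

    Uses FFT cross-correlations of the masked values, their squares and
    the masks to evaluate the per-lag Pearson formula over overlapping
    valid bins only.
    """
    za = np.where(mask_a, a, 0.0)
    zb = np.where(mask_b, b, 0.0)
    ma = mask_a.astype(float)
    mb = mask_b.astype(float)

    def cc(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        return fftconvolve(u, v[::-1, ::-1], mode="full")

    n = cc(ma, mb)
    sxy = cc(za, zb)
    sx = cc(za, mb)
    sy = cc(ma, zb)
    sxx = cc(za * za, mb)
    syy = cc(ma, zb * zb)
    n_round = np.round(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_x = n * sxx - sx * sx
        var_y = n * syy - sy * sy
        r = (n * sxy - sx * sy) / np.sqrt(var_x * var_y)
    bad = (n_round < min_overlap) | (var_x <= 1e-9) | (var_y <= 1e-9)
    r[bad] = np.nan
    return np.clip(r, -1.0, 1.0), n_round


def spatial_autocorrelogram(ratemap: RateMap2D,
                            min_overlap: int = MIN_OVERLAP
                            ) -> Autocorrelogram2D:
    """Spatial autocorrelogram of a rate map over visited bins."""
    vals = np.where(ratemap.mask, ratemap.rate, 0.0)
    if ratemap.mask.sum() < min_overlap:
        raise InputError("too few visited bins")
    if np.nanstd(ratemap.rate[ratemap.mask]) == 0:
        raise InputError("constant rate map: correlation undefined")
    r, n = _masked_crosscorr(vals, ratemap.mask, vals, ratemap.mask,
                             min_overlap)
    return Autocorrelogram2D(values=r, n_overlap=n, bin=ratemap.bin)


def cross_correlogram(map_a: RateMap2D, map_b: RateMap2D,
                      min_overlap: int = MIN_OVERLAP) -> Autocorrelogram2D:
    """Spatial cross-correlogram of two rate maps on the same grid."""
    if map_a.rate.shape != map_b.rate.shape:
        raise InputError("rate maps are not on the same grid")
    a = np.where(map_a.mask, map_a.rate, 0.0)
    b = np.where(map_b.mask, map_b.rate, 0.0)
    r, n = _masked_crosscorr(a, map_a.mask, b, map_b.mask, min_overlap)
    return Autocorrelogram2D(values=r, n_overlap=n, bin=map_a.bin)


# ---------------------------------------------------------------------------
# peaks, gridness, spacing
# ---------------------------------------------------------------------------

def _central_peak_radius(acorr: Autocorrelogram2D) -> float:
    """Extent (cm) of the contiguous region above 0.2 around zero lag."""
    v = np.nan_to_num(acorr.values, nan=-1.0)
    lab, _ = ndimage.label(v > CENTRAL_FLOOR)
    cy, cx = acorr.center
    centre_label = lab[cy, cx]
    if centre_label == 0:
        return acorr.bin
    dist = acorr.lag_distance()
    return float(dist[lab == centre_label].max()) + acorr.bin


def autocorr_peaks(acorr: Autocorrelogram2D,
                   floor: float = PEAK_FLOOR) -> np.ndarray:
    """Local maxima of the autocorrelogram outside the central peak.

    Returns an array of (row, col, distance_cm, value), sorted by distance
    from zero lag.
    """
    v = np.nan_to_num(acorr.values, nan=-np.inf)
    footprint = np.ones((3, 3), bool)
    is_max = (ndimage.maximum_filter(v, footprint=footprint) == v) & (v > floor)
    r0 = _central_peak_radius(acorr)
    dist = acorr.lag_distance()
    is_max &= dist > r0
    rows, cols = np.nonzero(is_max)
    if rows.size == 0:
        return np.empty((0, 4))
    # merge plateau duplicates: keep one maximum per labelled plateau
    lab, nlab = ndimage.label(is_max)
    out = []
    for k in range(1, nlab + 1):
        rr, cc = np.nonzero(lab == k)
        j = np.argmax(v[rr, cc])
        out.append((rr[j], cc[j], dist[rr[j], cc[j]], v[rr[j], cc[j]]))
    out = np.array(out)
    return out[np.argsort(out[:, 2])]


def _rotation_correlation(annulus_vals: np.ndarray, annulus_mask: np.ndarray,
                          angle: float) -> float:
    filled = np.where(annulus_mask, annulus_vals, 0.0)
    rot_v = ndimage.rotate(filled, angle, reshape=False, order=1)
    rot_m = ndimage.rotate(annulus_mask.astype(float), angle,
                           reshape=False, order=1) > 0.5
    both = annulus_mask & rot_m
    if both.sum() < MIN_OVERLAP:
        return np.nan
    a = annulus_vals[both]
    b = rot_v[both]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def gridness(acorr: Autocorrelogram2D, strict: bool = False,
             outer_margin: float = 1.1) -> float:
    """Rotational-symmetry grid score.

    The annulus between the central-peak radius and just beyond the six
    inner peaks is correlated with itself rotated by 60° and 120° (group
    1) versus 30°, 90° and 150° (group 2); the score is min(group 1) -
    max(group 2). With fewer than six peaks the score is NaN when
    ``strict``; otherwise a fallback annulus out to 70% of the map radius
    is used.
    """
    peaks = autocorr_peaks(acorr)
    r_in = _central_peak_radius(acorr)
    dist = acorr.lag_distance()
    if peaks.shape[0] >= 6:
        r_out = outer_margin * peaks[:6, 2].max()
    elif strict:
        return float("nan")
    else:
        r_out = 0.7 * dist.max() / np.sqrt(2)
    annulus = (dist > r_in) & (dist <= r_out) & np.isfinite(acorr.values)
    if annulus.sum() < MIN_OVERLAP:
        return float("nan")
    vals = np.nan_to_num(acorr.values, nan=0.0)
    g1 = [_rotation_correlation(vals, annulus, a) for a in (60, 120)]
    g2 = [_rotation_correlation(vals, annulus, a) for a in (30, 90, 150)]
    if np.any(np.isnan(g1)) or np.any(np.isnan(g2)):
        return float("nan")
    return float(min(g1) - max(g2))


def field_spacing_2d(acorr: Autocorrelogram2D) -> float:
    """Mean distance (cm) from zero lag to the six inner peaks."""
    peaks = autocorr_peaks(acorr)
    if peaks.shape[0] < 6:
        raise InsufficientDataError("fewer than six autocorrelogram peaks")
    return float(peaks[:6, 2].mean())


def grid_shuffle_threshold(cells: List[Tuple[Trajectory, SpikeTrain]],
                           spec: Optional[SmoothingSpec] = None,
                           n_per_cell: int = 400, percentile: float = 95.0,
                           seed: int = 0, min_shift: float = 20.0,
                           extent: Optional[float] = None
                           ) -> Tuple[float, np.ndarray]:
    """Grid-score threshold from time-rotated spike trains.

    Spike times of each cell are circularly rotated by a random offset
    drawn uniformly between ``min_shift`` s and duration - ``min_shift`` s;
    scores from all rotations of all cells are pooled and the stated
    percentile returned. Sessions shorter than 2·min_shift are skipped.
    """
    rng = np.random.default_rng(seed)
    scores = []
    for traj, spikes in cells:
        T = traj.duration
        if T < 2 * min_shift:
            import warnings
            warnings.warn("session shorter than 40 s skipped", stacklevel=2)
            continue
        for _ in range(n_per_cell):
            shift = rng.uniform(min_shift, T - min_shift)
            rolled = SpikeTrain(times=np.mod(spikes.times + shift, T))
            rm = compute_rate_map(traj, rolled, spec, extent=extent)
            try:
                g = gridness(spatial_autocorrelogram(rm))
            except InputError:
                continue
            if np.isfinite(g):
                scores.append(g)
    scores = np.asarray(scores)
    return float(np.percentile(scores, percentile)), scores


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------

def detect_fields(source: Union[RateMap2D, LinearizedActivity, np.ndarray],
                  min_pixels: Optional[int] = None,
                  threshold_frac: float = 0.30) -> FieldSet:
    """Connected regions above ``threshold_frac`` of the peak rate.

    2D maps use 8-connectivity and a 9-pixel minimum; 1D profiles use
    adjacency and a 5-pixel minimum.
    """
    if isinstance(source, RateMap2D):
        vals = np.nan_to_num(source.rate, nan=0.0)
        min_pixels = 9 if min_pixels is None else min_pixels
        two_d = True
        centers = None
        src = source
    else:
        if isinstance(source, LinearizedActivity):
            vals = np.nan_to_num(source.rate, nan=0.0)
            centers = source.centers
        else:
            vals = np.nan_to_num(np.asarray(source, dtype=float), nan=0.0)
            centers = np.arange(vals.size, dtype=float)
        min_pixels = 5 if min_pixels is None else min_pixels
        two_d = False
        src = None
    peak = vals.max()
    if peak <= 0:
        return FieldSet(fields=[])
    above = vals > threshold_frac * peak
    structure = np.ones((3, 3), bool) if two_d else None
    lab, nlab = ndimage.label(above, structure=structure)
    fields = []
    for k in range(1, nlab + 1):
        idx = np.nonzero(lab == k)
        if idx[0].size < min_pixels:
            continue
        w = vals[idx]
        if two_d:
            xc = 0.5 * (src.x_edges[:-1] + src.x_edges[1:])
            yc = 0.5 * (src.y_edges[:-1] + src.y_edges[1:])
            centroid = np.array([np.average(xc[idx[1]], weights=w),
                                 np.average(yc[idx[0]], weights=w)])
            flat = np.ravel_multi_index(idx, vals.shape)
        else:
            centroid = np.array([np.average(centers[idx[0]], weights=w)])
            flat = idx[0]
        fields.append(Field(indices=flat, peak_rate=float(w.max()),
                            centroid=centroid))
    return FieldSet(fields=fields)


def pair_phase_offset(a, b, environment: str = "arena"):
    """Spatial phase offset between two simultaneously recorded cells.

    Arena: offset (cm) of the cross-correlogram peak nearest zero lag,
    returned as (dx, dy). Track: absolute lag (cm) of the maximum of the
    cross-correlation of the two path-integrated profiles.
    """
    if environment == "arena":
        cc = cross_correlogram(a, b)
        peaks_v = np.nan_to_num(cc.values, nan=-np.inf)
        is_max = (ndimage.maximum_filter(peaks_v, size=3) == peaks_v) \
            & np.isfinite(cc.values) & (peaks_v > 0)
        if not is_max.any():
            raise InsufficientDataError("no cross-correlogram peak")
        dist = cc.lag_distance()
        rows, cols = np.nonzero(is_max)
        j = np.argmin(dist[rows, cols])
        cy, cx = cc.center
        return np.array([(cols[j] - cx) * cc.bin, (rows[j] - cy) * cc.bin])
    if environment == "track":
        from .coding import crosscorrelation_1d
        seq = crosscorrelation_1d(a, b)
        v = seq.values
        top = float(np.nanmax(v))
        # periodic profiles tie at every period: take the maximum nearest
        # zero lag, as in the arena convention
        near = np.isfinite(v) & (v >= top - 1e-9)
        lags = seq.lags[near]
        return float(abs(lags[np.argmin(np.abs(lags))]))
    raise ParameterError(f"unknown environment {environment!r}")
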