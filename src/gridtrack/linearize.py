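"""Linearization of track sessions into 1D reference frames.

Three frames are supported: *path-integrated distance* (signed cumulative
arc length, clockwise positive), *travelled distance* (absolute cumulative
arc length) and *elapsed time*. Laps are delimited where the signed
cumulative distance crosses multiples of the track circumference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .core import InputError, ParameterError, SpikeTrain, Trajectory


class InsufficientDataError(InputError):
    """Analysis skipped: not enough laps/spikes/coverage."""


FRAMES = ("path_integrated", "travelled", "time")
DEFAULT_BIN = {"path_integrated": 10.0, "travelled": 10.0, "time": 1.0}
STILL_SPEED = 0.5          # cm/s; slower samples are labelled "still"
DIRECTION_SMOOTH = 0.5     # s window for the direction label


@dataclass
class CumulativeDistanceSeries:
    """Per-sample cumulative arc lengths along the track.

    ``signed`` is positive for clockwise motion, ``absolute`` is
    non-decreasing; ``direction`` holds +1 (CW), -1 (CCW) or 0 (still).
    """

    t: np.ndarray
    signed: np.ndarray
    absolute: np.ndarray
    direction: np.ndarray

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def frame_coordinate(self, frame: str) -> np.ndarray:
        if frame == "path_integrated":
            return self.signed
        if frame == "travelled":
            return self.absolute
        if frame == "time":
            return self.t
        raise ParameterError(f"unknown frame {frame!r}")


@dataclass
class LinearizedActivity:
    """Firing activity binned along one 1D reference frame."""

    frame: str
    bin_width: float
    edges: np.ndarray          # len = nbins + 1
    counts: np.ndarray         # spikes per bin
    occupancy: np.ndarray      # seconds per bin

    def __post_init__(self) -> None:
        # "allocentric" (track position mod C) is a valid profile axis even
        # though it is not a frame spikes can be linearized into directly.
        if self.frame not in FRAMES + ("allocentric",):
            raise ParameterError(f"unknown frame {self.frame!r}")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def occupied(self) -> np.ndarray:
        return self.occupancy > 0

    @property
    def rate(self) -> np.ndarray:
        """Firing rate (Hz) per bin; NaN on unoccupied bins."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.counts / self.occupancy
        r[~self.occupied] = np.nan
        return r


@dataclass
class LapMatrix:
    """Per-lap firing rate versus position in the track."""

    rates: np.ndarray          # laps x nbins, NaN where unoccupied
    occupancy: np.ndarray      # laps x nbins, s
    counts: np.ndarray         # laps x nbins
    lap_ids: np.ndarray        # signed lap indices (floor(signed / C))
    circumference: float

    @property
    def n_laps(self) -> int:
        return int(self.rates.shape[0])

    @property
    def nbins(self) -> int:
        return int(self.rates.shape[1])

    @property
    def bin_width(self) -> float:
        return self.circumference / self.nbins


def unwrap_cumulative_angle(traj: Trajectory,
                            center: Tuple[float, float] = (0.0, 0.0),
                            radius: Optional[float] = None
                            ) -> CumulativeDistanceSeries:
    """Signed and absolute cumulative angular distance along the track.

    The per-sample arc increment is -r·Δθ with θ the unwrapped
    counter-clockwise angle about ``center``, so clockwise motion
    accumulates positive distance. ``radius`` is the scale of the angular
    distance; pass the track's nominal (outer) radius so that one lap
    accumulates exactly the 2π·R circumference used for lap segmentation
    (471 cm for R = 75 cm). When omitted, the per-sample-pair mean radius
    of the path is used (true arc length).
    """
    x = traj.x1 - center[0]
    y = traj.y1 - center[1]
    r = np.hypot(x, y)
    if np.any(r < 1e-9):
        raise InputError("sample at the track centre: angle undefined")
    theta = np.unwrap(np.arctan2(y, x))
    dtheta = np.diff(theta)
    rbar = radius if radius is not None else 0.5 * (r[:-1] + r[1:])
    steps = -rbar * dtheta
    signed = np.concatenate(([0.0], np.cumsum(steps)))
    absolute = np.concatenate(([0.0], np.cumsum(np.abs(steps))))

    # direction label from the smoothed angular speed
    dt = np.median(np.diff(traj.t))
    inst = np.concatenate(([steps[0] if steps.size else 0.0], steps)) / dt
    n = max(1, int(round(DIRECTION_SMOOTH / dt)))
    smooth = np.convolve(inst, np.ones(n) / n, mode="same")
    direction = np.sign(smooth) * (np.abs(smooth) >= STILL_SPEED)
    return CumulativeDistanceSeries(t=traj.t, signed=signed,
                                    absolute=absolute, direction=direction)


def segment_laps(series: CumulativeDistanceSeries, C: float) -> np.ndarray:
    """Per-sample lap index: floor(signed cumulative distance / C)."""
    if C <= 0:
        raise ParameterError("circumference must be positive")
    return np.floor(series.signed / C).astype(int)


def _spike_coords(spikes: SpikeTrain, t: np.ndarray,
                  coord: np.ndarray) -> np.ndarray:
    """Frame coordinate of each spike by linear interpolation in time."""
    return np.interp(spikes.times, t, coord)


def _make_edges(coord: np.ndarray, bin_width: float) -> np.ndarray:
    lo = np.floor(coord.min() / bin_width) * bin_width
    hi = np.ceil(coord.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n = int(round((hi - lo) / bin_width))
    return lo + bin_width * np.arange(n + 1)


def linearize_activity(spikes: SpikeTrain,
                       series: CumulativeDistanceSeries,
                       frame: str,
                       bin_width: Optional[float] = None,
                       sample_mask: Optional[np.ndarray] = None
                       ) -> LinearizedActivity:
    """Bin spikes and occupancy along one reference frame.

    Each spike is assigned the frame coordinate interpolated at its time;
    occupancy accumulates one tracking interval per sample. An optional
    boolean ``sample_mask`` restricts the analysis to a subset of samples
    (spikes are kept when the nearest sample is included).
    """
    if frame not in FRAMES:
        raise ParameterError(f"unknown frame {frame!r}")
    bin_width = bin_width or DEFAULT_BIN[frame]
    coord = series.frame_coordinate(frame)
    dt = series.dt
    sc = _spike_coords(spikes, series.t, coord)
    if sample_mask is not None:
        keep_idx = np.searchsorted(series.t, spikes.times).clip(0, series.t.size - 1)
        sc = sc[sample_mask[keep_idx]]
        coord_occ = coord[sample_mask]
    else:
        coord_occ = coord
    edges = _make_edges(coord, bin_width)
    occ, _ = np.histogram(coord_occ, bins=edges)
    counts, _ = np.histogram(sc, bins=edges)
    return LinearizedActivity(frame=frame, bin_width=bin_width, edges=edges,
                              counts=counts.astype(float),
                              occupancy=occ.astype(float) * dt)


def lap_position_matrix(spikes: SpikeTrain,
                        series: CumulativeDistanceSeries,
                        C: float, nbins: int = 47) -> LapMatrix:
    """Firing rate per (lap, track-position) bin.

    Position is the signed cumulative distance modulo C; the bin width is
    C/nbins so the bins tile the circle exactly. Requires at least two
    laps' worth of samples.
    """
    lap = segment_laps(series, C)
    lap_ids = np.unique(lap)
    if lap_ids.size < 2:
        raise InsufficientDataError("fewer than 2 laps; lap analysis skipped")
    pos = np.mod(series.signed, C)
    spike_pos = np.mod(_spike_coords(spikes, series.t, series.signed), C)
    spike_lap_raw = np.interp(spikes.times, series.t, series.signed)
    spike_lap = np.floor(spike_lap_raw / C).astype(int)
    dt = series.dt
    edges = np.linspace(0.0, C, nbins + 1)
    L = lap_ids.size
    occ = np.zeros((L, nbins))
    cnt = np.zeros((L, nbins))
    lap_row = {k: i for i, k in enumerate(lap_ids)}
    rows = np.array([lap_row[k] for k in lap])
    np.add.at(occ, (rows, np.clip(np.digitize(pos, edges) - 1, 0, nbins - 1)), dt)
    if spike_pos.size:
        srows = np.array([lap_row.get(k, -1) for k in spike_lap])
        ok = srows >= 0
        np.add.at(cnt, (srows[ok],
                        np.clip(np.digitize(spike_pos[ok], edges) - 1, 0, nbins - 1)),
                  1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = cnt / occ
    rates[occ == 0] = np.nan
    return LapMatrix(rates=rates, occupancy=occ, counts=cnt,
                     lap_ids=lap_ids, circumference=C)


def directional_split(spikes: SpikeTrain,
                      series: CumulativeDistanceSeries,
                      bin_width: float = 10.0,
                      min_bins: int = 10
                      ) -> Tuple[LinearizedActivity, LinearizedActivity, float]:
    """Path-integrated profiles restricted to CW and CCW runs.

    Returns the two profiles and their Pearson correlation over mutually
    occupied bins. Still samples are excluded.
    """
    cw = series.direction > 0
    ccw = series.direction < 0
    if cw.sum() == 0 or ccw.sum() == 0:
        raise InsufficientDataError("one running direction is empty")
    prof_cw = linearize_activity(spikes, series, "path_integrated",
                                 bin_width, sample_mask=cw)
    prof_ccw = linearize_activity(spikes, series, "path_integrated",
                                  bin_width, sample_mask=ccw)
    # correlate on a common grid
    lo = min(prof_cw.edges[0], prof_ccw.edges[0])
    hi = max(prof_cw.edges[-1], prof_ccw.edges[-1])
    n = int(round((hi - lo) / bin_width))
    grid = lo + bin_width * (np.arange(n) + 0.5)

    def on_grid(p: LinearizedActivity) -> Tuple[np.ndarray, np.ndarray]:
        idx = np.clip(((grid - p.edges[0]) / bin_width).astype(int), 0,
                      p.counts.size - 1)
        inside = (grid >= p.edges[0]) & (grid <= p.edges[-1])
        r = np.full(n, np.nan)
        r[inside] = p.rate[idx[inside]]
        return r

    a, b = on_grid(prof_cw), on_grid(prof_ccw)
    both = np.isfinite(a) & np.isfinite(b)
    if both.sum() < min_bins:
        raise InsufficientDataError("fewer than %d mutually occupied bins"
                                    % min_bins)
    if np.std(a[both]) == 0 or np.std(b[both]) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(a[both], b[both])[0, 1])
    return prof_cw, prof_ccw, r
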