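"""Core data containers shared by every analysis stage.

Positions are in centimetres, with the origin at the enclosure centre,
x rightward and y upward; angles are degrees counter-clockwise from +x.
Times are in seconds. A trajectory carries two head-mounted markers
(front and back, nominally 5 cm apart) so that heading is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class GridtrackError(Exception):
    """Base class for package errors."""


class ParameterError(GridtrackError):
    """Invalid parameter value."""


class InputError(GridtrackError):
    """Invalid or inconsistent input data."""


class LoadError(GridtrackError):
    """A session on disk failed validation; message names the record."""


@dataclass
class Trajectory:
    """Timestamped 2D head positions of the two markers.

    ``x1, y1`` is the front (position) marker, ``x2, y2`` the back marker.
    The position of the animal is taken from the front marker.
    """

    t: np.ndarray
    x1: np.ndarray
    y1: np.ndarray
    x2: Optional[np.ndarray] = None
    y2: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x1 = np.asarray(self.x1, dtype=float)
        self.y1 = np.asarray(self.y1, dtype=float)
        if self.x2 is not None:
            self.x2 = np.asarray(self.x2, dtype=float)
            self.y2 = np.asarray(self.y2, dtype=float)
        if self.t.size < 2:
            raise InputError("trajectory needs at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise InputError("trajectory timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0] + self.dt)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def has_heading(self) -> bool:
        return self.x2 is not None

    def speed(self, smooth_window: float = 0.5) -> np.ndarray:
        """Instantaneous speed (cm/s) from position differences.

        Smoothed with a boxcar of ``smooth_window`` seconds (0 disables).
        """
        dx = np.diff(self.x1)
        dy = np.diff(self.y1)
        step = np.hypot(dx, dy)
        v = np.empty_like(self.t)
        v[1:] = step / np.diff(self.t)
        v[0] = v[1]
        if smooth_window > 0:
            n = max(1, int(round(smooth_window / self.dt)))
            kernel = np.ones(n) / n
            v = np.convolve(v, kernel, mode="same")
        return v

    def heading(self) -> np.ndarray:
        """Head direction in degrees CCW from +x (front minus back marker)."""
        if not self.has_heading:
            raise InputError("trajectory has no second marker; heading undefined")
        return np.degrees(np.arctan2(self.y1 - self.y2, self.x1 - self.x2)) % 360.0


@dataclass
class SpikeTrain:
    """Sorted spike times (s) of one unit within a session."""

    times: np.ndarray
    unit_id: str = "unit0"

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float))

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class LFPSignal:
    """Single-channel local field potential trace."""

    values: np.ndarray
    sample_rate: float = 1024.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.values.size / self.sample_rate


@dataclass
class CueCard:
    """White cue card attached to the outer wall."""

    angle_deg: float = 90.0
    width_cm: float = 30.0
    present: bool = True


@dataclass
class SessionManifest:
    """Enclosure geometry and file layout of one recording session."""

    enclosure: str = "track"            # "arena" | "track"
    radius_outer: float = 75.0          # cm
    track_width: float = 15.0           # cm (ignored for arenas)
    condition: str = "light"            # "light" | "dark"
    cue: CueCard = field(default_factory=CueCard)
    tracking_rate: float = 50.0         # samples/s
    lfp_rate: float = 1024.0
    tracking_file: str = "tracking.csv"
    spike_files: dict = field(default_factory=dict)   # unit_id -> filename
    lfp_file: Optional[str] = None

    def __post_init__(self) -> None:
        if self.enclosure not in ("arena", "track"):
            raise ParameterError(f"unknown enclosure {self.enclosure!r}")
        if self.radius_outer <= 0 or self.track_width <= 0:
            raise ParameterError("geometry values must be positive")
        if self.cue.present and self.cue.width_cm >= 2 * np.pi * self.radius_outer:
            raise ParameterError("cue card wider than the outer circumference")

    @property
    def radius_inner(self) -> float:
        return self.radius_outer - self.track_width

    @property
    def radius_mid(self) -> float:
        return self.radius_outer - self.track_width / 2.0

    @property
    def circumference(self) -> float:
        """Track length 2π·R at the nominal (outer) radius, cm.

        Cumulative track distances are angular distances scaled by the
        nominal radius, so one full lap always accumulates exactly this
        circumference regardless of the animal's radial position within
        the 15 cm annulus (471 cm for the ∅150 cm enclosure).
        """
        return float(2 * np.pi * self.radius_outer)


@dataclass
class Session:
    """One recording session: trajectory, spike trains, optional LFP."""

    trajectory: Trajectory
    spikes: list
    lfp: Optional[LFPSignal] = None
    manifest: SessionManifest = field(default_factory=SessionManifest)
    ground_truth: Optional[dict] = None   # unit_id -> GroundTruth (synthetic only)

    def validate(self) -> None:
        dur = self.trajectory.t[-1] + self.trajectory.dt
        for st in self.spikes:
            if st.n_spikes and (st.times[0] < 0 or st.times[-1] > dur):
                bad = st.times[-1] if st.times[-1] > dur else st.times[0]
                raise LoadError(
                    f"unit {st.unit_id!r}: spike at t={bad:.4f} s outside "
                    f"session [0, {dur:.4f}]"
                )
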