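"""Synthetic sessions with known ground truth.

Emulates free foraging in a circular arena (∅150 or ∅100 cm) and on the
15 cm wide circular track obtained by inserting an inner wall, together
with spike trains generated under each candidate coding scheme
(allocentric position, path-integrated distance, travelled distance,
elapsed time, or a slice through a 2D hexagonal lattice), LFP traces with
speed-modulated theta, and head-direction / speed-tuned cells.

Default behaviour parameters reproduce the published summary statistics of
track foraging: roughly three net laps, ~42 m travelled and ~98 direction
reversals per 10 minute session, with a time-averaged speed of ~7 cm/s on
the track and ~14 cm/s in the arena. Reversals follow a two-state Markov
direction process with an asymmetric dwell (the animal spends about two
thirds of its time running in a session-preferred direction): a symmetric
reversal process cannot jointly produce ~3 net laps and ~9 lap-lengths of
travelled distance, whereas the asymmetric one does.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional
import warnings

import numpy as np
from scipy.special import i0

from .core import (
    CueCard,
    InputError,
    LFPSignal,
    ParameterError,
    Session,
    SessionManifest,
    SpikeTrain,
    Trajectory,
)

MARKER_SEPARATION = 5.0  # cm between the two head markers


@dataclass
class BehaviorParams:
    """Movement-statistics parameters of a simulated session."""

    enclosure: str = "track"          # "arena" | "track"
    radius_outer: float = 75.0        # cm
    track_width: float = 15.0         # cm
    duration: float = 600.0           # s
    sample_rate: float = 50.0         # samples/s
    mean_speed: float = 7.0           # cm/s, time-averaged (incl. pauses)
    turn_rate: float = 9.8            # track: reversals/min; arena: rad^2/s
    direction_bias: float = 2.0 / 3.0  # fraction of time in preferred direction
    speed_sd: float = 3.0             # cm/s, OU stationary sd
    speed_tau: float = 2.0            # s, OU relaxation time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ParameterError("duration and sample_rate must be positive")
        if self.mean_speed < 0:
            raise ParameterError("mean_speed must be non-negative")
        if self.enclosure not in ("arena", "track"):
            raise ParameterError(f"unknown enclosure {self.enclosure!r}")

    @classmethod
    def track(cls, **kw) -> "BehaviorParams":
        return cls(enclosure="track", **kw)

    @classmethod
    def arena(cls, **kw) -> "BehaviorParams":
        kw.setdefault("mean_speed", 14.0)
        kw.setdefault("turn_rate", 1.0)
        kw.setdefault("speed_sd", 5.0)
        return cls(enclosure="arena", **kw)

    @property
    def radius_mid(self) -> float:
        return self.radius_outer - self.track_width / 2.0


@dataclass
class GroundTruth:
    """Generative parameters of one synthetic cell."""

    coding_model: str = "path_integrated"
    # 1D models: Gaussian bump profile on the model's axis
    field_width: float = 10.0      # Gaussian sigma, cm (or s for "time")
    first_offset: float = 50.0     # cm (or s)
    spacing: float = 150.0         # cm (or s)
    peak_rate: float = 8.0         # Hz
    # 2D lattice (for "slice2d" and arena generation)
    lattice_spacing: float = 50.0  # cm
    orientation_deg: float = 0.0
    phase: tuple = (0.0, 0.0)      # cm offset of the lattice
    field_width_2d: float = 8.0    # Gaussian sigma of lattice bumps, cm

    VALID_MODELS = (
        "allocentric",
        "path_integrated",
        "travelled",
        "time",
        "slice2d",
        "none",
    )

    def __post_init__(self) -> None:
        if self.coding_model not in self.VALID_MODELS:
            raise ParameterError(f"unknown coding model {self.coding_model!r}")
        if self.spacing <= 0 or self.lattice_spacing <= 0:
            raise ParameterError("spacing must be positive")
        if self.peak_rate < 0:
            raise ParameterError("peak_rate must be non-negative")

    def to_dict(self) -> dict:
        return {
            "coding_model": self.coding_model,
            "field_width": self.field_width,
            "first_offset": self.first_offset,
            "spacing": self.spacing,
            "peak_rate": self.peak_rate,
            "lattice_spacing": self.lattice_spacing,
            "orientation_deg": self.orientation_deg,
            "phase": list(self.phase),
            "field_width_2d": self.field_width_2d,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["phase"] = tuple(d.get("phase", (0.0, 0.0)))
        return cls(**d)


@dataclass
class TuningSpec:
    """Head-direction or speed tuning of a simulated conjunctive cell."""

    kind: str = "head_direction"   # "head_direction" | "speed"
    pfd: float = 0.0               # deg
    concentration: float = 4.0     # von Mises kappa
    baseline_rate: float = 5.0     # Hz (mean rate of the HD cell)
    slope: float = 0.5             # Hz per cm/s (speed cells)
    intercept: float = 1.0         # Hz (speed cells)

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ParameterError("concentration must be non-negative")
        if self.kind not in ("head_direction", "speed"):
            raise ParameterError(f"unknown tuning kind {self.kind!r}")


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def _ou_series(n: int, dt: float, mean: float, sd: float, tau: float,
               rng: np.random.Generator) -> np.ndarray:
    """Ornstein–Uhlenbeck sample path via exact discretisation."""
    if sd == 0 or n == 0:
        return np.full(n, mean)
    a = np.exp(-dt / tau)
    noise_sd = sd * np.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n)
    # x[i] = a x[i-1] + c[i], started at the stationary distribution
    c = (1 - a) * mean + noise_sd * eps
    c[0] = mean + sd * eps[0]
    x = np.empty(n)
    acc = 0.0
    for i in range(n):  # n ~ 3e4: fine
        acc = a * acc + c[i]
        x[i] = acc
    return x


def _direction_series(t: np.ndarray, flips_per_s: float, bias: float,
                      rng: np.random.Generator) -> np.ndarray:
    """±1 direction labels from a two-state Markov process.

    ``bias`` is the stationary fraction of time spent in the (randomly
    signed) preferred direction; the total flip rate is ``flips_per_s``.
    """
    duration = t[-1] - t[0]
    preferred = rng.choice([-1.0, 1.0])
    if flips_per_s <= 0:
        return np.full(t.size, preferred)
    rate_leave_pref = flips_per_s / (2.0 * bias)
    rate_leave_other = flips_per_s / (2.0 * (1.0 - bias))
    # alternate exponential dwells starting in the preferred state
    times = [0.0]
    state = 1  # 1 = preferred
    now = 0.0
    while now < duration:
        rate = rate_leave_pref if state == 1 else rate_leave_other
        now += rng.exponential(1.0 / rate)
        times.append(now)
        state = -state
    # state during [times[k], times[k+1]) alternates starting at preferred
    idx = np.searchsorted(np.asarray(times), t - t[0], side="right") - 1
    signs = np.where(idx % 2 == 0, 1.0, -1.0)
    return preferred * signs


def simulate_trajectory(params: BehaviorParams) -> Trajectory:
    """Simulate a foraging path in the arena or on the circular track.

    Track paths are 1D stochastic walks in angle: an OU speed process
    (clipped at zero) signed by a two-state Markov direction process, plus
    a small radial jitter confined to the annulus. Arena paths are smooth
    2D random walks with diffusing heading, reflected at the wall.
    Both markers are returned (5 cm apart along the heading).
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sample_rate))
    dt = 1.0 / params.sample_rate
    t = np.arange(n) * dt

    if params.enclosure == "track":
        speed_sd = params.speed_sd if params.mean_speed > 0 else 0.0
        speed = _ou_series(n, dt, params.mean_speed, speed_sd,
                           params.speed_tau, rng)
        speed = np.clip(speed, 0.0, None)
        direction = _direction_series(t, params.turn_rate / 60.0,
                                      params.direction_bias, rng)
        r_mid = params.radius_mid
        omega = direction * speed / r_mid          # rad/s, CCW positive
        theta = rng.uniform(0, 2 * np.pi) + np.concatenate(
            ([0.0], np.cumsum(omega[:-1] * dt)))
        # radial jitter, confined to the annulus with 1.5 cm margin
        r_jit = _ou_series(n, dt, 0.0, 2.0 if params.mean_speed > 0 else 0.0,
                           1.0, rng)
        half = params.track_width / 2.0 - 1.5
        r = r_mid + np.clip(r_jit, -max(half, 0.0), max(half, 0.0))
        x = r * np.cos(theta)
        y = r * np.sin(theta)
        head = theta + np.where(direction >= 0, 0.5, -0.5) * np.pi
    else:
        speed = _ou_series(n, dt, params.mean_speed, params.speed_sd,
                           params.speed_tau, rng)
        speed = np.clip(speed, 0.0, None)
        r_max = params.radius_outer - 2.0
        x = np.empty(n)
        y = np.empty(n)
        head = np.empty(n)
        hd = rng.uniform(0, 2 * np.pi)
        turn_sd = np.sqrt(max(params.turn_rate, 0.0) * dt)
        turns = rng.standard_normal(n) * turn_sd
        xi, yi = rng.uniform(-r_max / 2, r_max / 2, size=2)
        for i in range(n):
            x[i], y[i], head[i] = xi, yi, hd
            hd += turns[i]
            nx = xi + speed[i] * dt * np.cos(hd)
            ny = yi + speed[i] * dt * np.sin(hd)
            if np.hypot(nx, ny) > r_max:
                # steer back toward the centre with some scatter
                hd = np.arctan2(-yi, -xi) + 0.5 * turns[i] / max(turn_sd, 1e-9)
                nx = xi + speed[i] * dt * np.cos(hd)
                ny = yi + speed[i] * dt * np.sin(hd)
                if np.hypot(nx, ny) > r_max:
                    nx, ny = xi, yi
            xi, yi = nx, ny

    x2 = x - MARKER_SEPARATION * np.cos(head)
    y2 = y - MARKER_SEPARATION * np.sin(head)
    return Trajectory(t=t, x1=x, y1=y, x2=x2, y2=y2)


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------

def _poisson_spikes(rate: np.ndarray, t: np.ndarray, dt: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson spikes from a piecewise-constant rate."""
    counts = rng.poisson(np.clip(rate, 0.0, None) * dt)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    starts = np.repeat(t, counts)
    return np.sort(starts + rng.uniform(0.0, dt, size=total))


def lattice_rate(x: np.ndarray, y: np.ndarray, gt: GroundTruth) -> np.ndarray:
    """Firing rate of a hexagonal lattice of Gaussian bumps at (x, y)."""
    a = gt.lattice_spacing
    phi = np.radians(gt.orientation_deg)
    v1 = a * np.array([np.cos(phi), np.sin(phi)])
    v2 = a * np.array([np.cos(phi + np.pi / 3), np.sin(phi + np.pi / 3)])
    px = np.asarray(x) - gt.phase[0]
    py = np.asarray(y) - gt.phase[1]
    # node indices near each sample via the inverse lattice basis
    basis = np.column_stack([v1, v2])
    inv = np.linalg.inv(basis)
    ij = inv @ np.vstack([px.ravel(), py.ravel()])
    rate = np.zeros(px.size)
    i0_ = np.floor(ij[0])
    j0_ = np.floor(ij[1])
    sig2 = 2.0 * gt.field_width_2d ** 2
    for di in (0, 1, -1, 2):
        for dj in (0, 1, -1, 2):
            nx = (i0_ + di) * v1[0] + (j0_ + dj) * v2[0]
            ny = (i0_ + di) * v1[1] + (j0_ + dj) * v2[1]
            d2 = (px.ravel() - nx) ** 2 + (py.ravel() - ny) ** 2
            rate += np.exp(-d2 / sig2)
    return (gt.peak_rate * rate).reshape(np.shape(px))


def generate_grid_spikes_2d(traj: Trajectory, gt: GroundTruth,
                            seed: int = 0) -> SpikeTrain:
    """Spikes of a 2D grid cell along an arena trajectory."""
    rng = np.random.default_rng(seed)
    r = np.hypot(traj.x1, traj.y1)
    rate = lattice_rate(traj.x1, traj.y1, gt)
    if np.all(r > 40.0) and np.ptp(r) < 20.0:
        warnings.warn("trajectory looks like a track; 2D lattice sampled on "
                      "an annulus only", stacklevel=2)
    times = _poisson_spikes(rate, traj.t, traj.dt, rng)
    return SpikeTrain(times=times)


def _periodic_bump_rate(coord: np.ndarray, gt: GroundTruth) -> np.ndarray:
    """Rate of Gaussian bumps repeating every ``gt.spacing`` along ``coord``."""
    d = np.mod(coord - gt.first_offset, gt.spacing)
    d = np.minimum(d, gt.spacing - d)
    return gt.peak_rate * np.exp(-(d ** 2) / (2.0 * gt.field_width ** 2))


def generate_track_spikes(traj: Trajectory, gt: GroundTruth,
                          seed: int = 0,
                          circumference: Optional[float] = None,
                          reference_radius: Optional[float] = None
                          ) -> SpikeTrain:
    """Spikes on the track under one of the five candidate coding models.

    ``reference_radius`` sets the angular-distance scale (pass the track's
    nominal outer radius so ground-truth spacings live on the same axis
    the analyses use); defaults to the mean path radius.
    """
    from .linearize import unwrap_cumulative_angle

    rng = np.random.default_rng(seed)
    model = gt.coding_model
    if model == "none":
        return SpikeTrain(times=np.empty(0))
    if model == "slice2d":
        rate = lattice_rate(traj.x1, traj.y1, gt)
    else:
        series = unwrap_cumulative_angle(traj, radius=reference_radius)
        if model == "path_integrated":
            coord = series.signed
        elif model == "travelled":
            coord = series.absolute
        elif model == "time":
            coord = traj.t
        elif model == "allocentric":
            if circumference is None:
                rr = reference_radius or np.mean(np.hypot(traj.x1, traj.y1))
                circumference = 2 * np.pi * rr
            C = circumference
            coord = np.mod(series.signed, C)
            # wrap-aware: fields repeat with the track, not with spacing only
            d = np.abs(coord[:, None] -
                       _allocentric_centres(gt, C)[None, :])
            d = np.minimum(d, C - d)
            rate = gt.peak_rate * np.exp(
                -(d.min(axis=1) ** 2) / (2.0 * gt.field_width ** 2))
            times = _poisson_spikes(rate, traj.t, traj.dt, rng)
            return SpikeTrain(times=times)
        else:
            raise ParameterError(f"unknown coding model {model!r}")
        rate = _periodic_bump_rate(coord, gt)
    times = _poisson_spikes(rate, traj.t, traj.dt, rng)
    return SpikeTrain(times=times)


def _allocentric_centres(gt: GroundTruth, C: float) -> np.ndarray:
    """Field centres of an allocentric cell, fixed in track coordinates."""
    k = int(np.ceil(C / gt.spacing))
    return np.mod(gt.first_offset + gt.spacing * np.arange(k), C)


def generate_drifting_spikes(traj: Trajectory, gt: GroundTruth,
                             seed: int = 0,
                             noise_sd: float = 5.0,
                             anchoring: float = 0.5,
                             noise_region=None,
                             reference_radius: Optional[float] = None
                             ) -> SpikeTrain:
    """Track-anchored cell whose fields drift from lap to lap.

    The field pattern of an allocentric cell is displaced on lap ``k`` by
    an AR(1) offset ``o_k = (1 - anchoring) * o_(k-1) + noise_sd * eps_k``
    (cm): ``anchoring`` 1 gives independent per-lap noise, 0 a random
    walk, and smaller ``noise_sd`` a more stable map. When
    ``noise_region`` is given (an object with a ``contains(angles_deg)``
    method, e.g. :class:`gridtrack.cue.Arc`), the displacement applies
    only at samples whose track angle lies inside that region — fields
    elsewhere stay put. Used to emulate cue-controlled stabilisation and
    light/dark manipulations.
    """
    from .linearize import segment_laps, unwrap_cumulative_angle

    if not (0.0 <= anchoring <= 1.0):
        raise ParameterError("anchoring must be in [0, 1]")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rr = reference_radius or float(np.mean(np.hypot(traj.x1, traj.y1)))
    C = 2.0 * np.pi * rr
    series = unwrap_cumulative_angle(traj, radius=rr)
    lap = segment_laps(series, C)
    ids = np.unique(lap)
    offsets = {}
    o = 0.0
    for k in ids:
        o = (1.0 - anchoring) * o + noise_sd * rng.standard_normal()
        offsets[int(k)] = o
    off = np.array([offsets[int(k)] for k in lap])
    ang = np.degrees(np.arctan2(traj.y1, traj.x1))
    if noise_region is not None:
        off = np.where(noise_region.contains(ang), off, 0.0)
    # room-anchored track position (cm along the circumference, CW positive)
    # so the same ground truth yields the same fields across sessions
    coord = np.mod(-rr * np.radians(ang) - off, C)
    d = np.abs(coord[:, None] - _allocentric_centres(gt, C)[None, :])
    d = np.minimum(d, C - d)
    rate = gt.peak_rate * np.exp(
        -(d.min(axis=1) ** 2) / (2.0 * gt.field_width ** 2))
    return SpikeTrain(times=_poisson_spikes(rate, traj.t, traj.dt, rng))


# ---------------------------------------------------------------------------
# LFP and tuned cells
# ---------------------------------------------------------------------------

def generate_lfp(traj: Trajectory, f0: float = 8.0,
                 speed_slope: float = 0.01, amplitude: float = 1.0,
                 noise_sd: float = 0.2, seed: int = 0,
                 sample_rate: float = 1024.0) -> LFPSignal:
    """Frequency-modulated theta trace, f(t) = f0 + slope · speed(t)."""
    if not (4.0 <= f0 <= 12.0):
        warnings.warn(f"f0 = {f0} Hz outside the theta band", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = int(round(traj.duration * sample_rate))
    tl = np.arange(n) / sample_rate
    speed = np.interp(tl, traj.t, traj.speed())
    finst = f0 + speed_slope * speed
    phase = 2.0 * np.pi * np.cumsum(finst) / sample_rate
    v = amplitude * np.sin(phase)
    if noise_sd > 0:
        v = v + noise_sd * rng.standard_normal(n)
    return LFPSignal(values=v, sample_rate=sample_rate)


def generate_tuned_spikes(traj: Trajectory, spec: TuningSpec,
                          seed: int = 0) -> SpikeTrain:
    """Poisson spikes with von Mises HD tuning or linear speed tuning."""
    rng = np.random.default_rng(seed)
    if spec.kind == "head_direction":
        if not traj.has_heading:
            raise InputError("head-direction tuning requires two markers")
        h = np.radians(traj.heading())
        kappa = spec.concentration
        rate = spec.baseline_rate * np.exp(
            kappa * np.cos(h - np.radians(spec.pfd))) / i0(kappa)
    else:
        rate = np.clip(spec.intercept + spec.slope * traj.speed(), 0.0, None)
    times = _poisson_spikes(rate, traj.t, traj.dt, rng)
    return SpikeTrain(times=times)


def generate_modulated_spikes(duration: float, mean_rate: float = 20.0,
                              freq: float = 8.0, depth: float = 0.8,
                              refractory: float = 0.0,
                              seed: int = 0) -> SpikeTrain:
    """Poisson spikes rate-modulated at ``freq`` Hz (theta surrogate).

    rate(t) = mean_rate · (1 + depth·sin(2π·freq·t)); an optional
    absolute refractory period is enforced by dropping violating spikes.
    ``depth`` 0 gives a homogeneous Poisson train.
    """
    if not (0.0 <= depth <= 1.0):
        raise ParameterError("depth must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dt = 1e-3
    t = np.arange(int(round(duration / dt))) * dt
    rate = mean_rate * (1.0 + depth * np.sin(2.0 * np.pi * freq * t))
    times = _poisson_spikes(rate, t, dt, rng)
    if refractory > 0 and times.size:
        kept = [times[0]]
        for s in times[1:]:
            if s - kept[-1] >= refractory:
                kept.append(s)
        times = np.asarray(kept)
    return SpikeTrain(times=times)


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

def simulate_session(params: BehaviorParams,
                     cells: Optional[list] = None,
                     with_lfp: bool = False,
                     condition: str = "light",
                     cue: Optional[CueCard] = None) -> Session:
    """Simulate a full session: trajectory, one spike train per cell spec.

    ``cells`` is a list of GroundTruth (track/arena cells) or TuningSpec
    entries; each cell draws its own seed from the session seed.
    """
    traj = simulate_trajectory(params)
    cells = cells or []
    rng = np.random.default_rng(params.seed + 1)
    spikes = []
    truth = {}
    for i, spec in enumerate(cells):
        cseed = int(rng.integers(0, 2 ** 31 - 1))
        uid = f"unit{i}"
        if isinstance(spec, TuningSpec):
            st = generate_tuned_spikes(traj, spec, seed=cseed)
        elif params.enclosure == "arena":
            st = generate_grid_spikes_2d(traj, spec, seed=cseed)
        else:
            st = generate_track_spikes(
                traj, spec, seed=cseed,
                circumference=2 * np.pi * params.radius_outer,
                reference_radius=params.radius_outer)
        st.unit_id = uid
        spikes.append(st)
        truth[uid] = spec
    lfp = None
    if with_lfp:
        lfp = generate_lfp(traj, seed=params.seed + 2)
    manifest = SessionManifest(
        enclosure=params.enclosure,
        radius_outer=params.radius_outer,
        track_width=params.track_width,
        condition=condition,
        cue=cue or CueCard(present=(condition == "light")),
        tracking_rate=params.sample_rate,
        spike_files={s.unit_id: f"{s.unit_id}.spikes" for s in spikes},
        lfp_file="lfp.csv" if with_lfp else None,
    )
    return Session(trajectory=traj, spikes=spikes, lfp=lfp,
                   manifest=manifest, ground_truth=truth)
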