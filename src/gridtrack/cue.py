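"""Cue-card visibility geometry and cue-dependence analyses.

The cue card hangs on the outer wall of the circular track; the inner
wall occludes it from part of the track. The visible arc is obtained
analytically from the tangents drawn from the card borders to the inner
circle, intercepted with the circle of the animal's trajectory
(mid-track), and cross-checked by brute-force ray casting. Firing
stability and field density are then compared between the visible-cue
region and an equally sized diametrically opposite region, with an
ambiguous buffer excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import InputError, ParameterError, SpikeTrain, Trajectory
from .linearize import (
    CumulativeDistanceSeries,
    InsufficientDataError,
    LinearizedActivity,
    linearize_activity,
)

CONVENTIONS = ("any-point", "whole-card")
MIN_OVERLAP_PROFILE = 10       # bins required for a profile correlation


def _circdiff(a: np.ndarray, b: float) -> np.ndarray:
    """Signed angular difference a - b wrapped to (-180, 180] degrees."""
    return (np.asarray(a, dtype=float) - b + 180.0) % 360.0 - 180.0


@dataclass
class Arc:
    """Angular interval on the track, centre and extent in degrees."""

    center_deg: float
    extent_deg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.extent_deg <= 360.0):
            raise ParameterError("arc extent must be in [0, 360] degrees")
        self.center_deg = float(self.center_deg % 360.0)

    @property
    def lo(self) -> float:
        return self.center_deg - self.extent_deg / 2.0

    @property
    def hi(self) -> float:
        return self.center_deg + self.extent_deg / 2.0

    def contains(self, angles_deg) -> np.ndarray:
        """Boolean mask: which angles (degrees) fall inside the arc."""
        d = np.abs(_circdiff(angles_deg, self.center_deg))
        return d <= self.extent_deg / 2.0


@dataclass
class TrackGeometry:
    """Wall radii and cue-card placement of the circular track."""

    radius_outer: float = 75.0     # cm
    radius_inner: float = 60.0     # cm (outer - track width)
    radius_mid: float = 67.5       # cm, animal's trajectory circle
    card_angle_deg: float = 90.0
    card_width_cm: float = 30.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.radius_inner < self.radius_mid
                < self.radius_outer):
            raise ParameterError(
                "need 0 <= inner < mid < outer radius "
                f"(got {self.radius_inner}, {self.radius_mid}, "
                f"{self.radius_outer})")
        if self.card_width_cm <= 0:
            raise ParameterError("card width must be positive")
        if self.card_width_cm >= 2 * np.pi * self.radius_outer:
            raise ParameterError("card wider than the outer circumference")

    @property
    def card_arc(self) -> Arc:
        """Angular extent of the card on the outer wall."""
        return Arc(self.card_angle_deg,
                   np.degrees(self.card_width_cm / self.radius_outer))


def _tangent_halfwidth(geom: TrackGeometry) -> float:
    """Max angular separation (deg) between a card border point and a
    mid-circle point joined by a sight line grazing the inner wall.

    The limiting sight line is the common tangent to the inner circle
    through both points: the tangent point splits the separation into
    arccos(r/R_outer) + arccos(r/R_mid).
    """
    r = geom.radius_inner
    if r <= 0:
        return 180.0
    return float(np.degrees(np.arccos(r / geom.radius_outer)
                            + np.arccos(r / geom.radius_mid)))


def visible_arc(geom: TrackGeometry,
                convention: str = "any-point") -> Arc:
    """Mid-track angles from which the cue card can be seen.

    A point sees the card when a straight sight line to a card point
    does not cross the inner wall. ``convention`` selects whether one
    visible card point suffices ("any-point", default) or the whole
    card must be visible ("whole-card"); which one matches a given
    experimental definition is ambiguous, so the choice is exposed
    rather than asserted.
    """
    if convention not in CONVENTIONS:
        raise ParameterError(f"unknown visibility convention {convention!r}")
    delta = _tangent_halfwidth(geom)
    card = geom.card_arc.extent_deg
    if convention == "any-point":
        extent = card + 2.0 * delta
    else:
        extent = max(2.0 * delta - card, 0.0)
    return Arc(geom.card_angle_deg, min(extent, 360.0))


def visible_arc_raycast(geom: TrackGeometry,
                        convention: str = "any-point",
                        angle_step_deg: float = 1.0,
                        card_step_cm: float = 1.0) -> Arc:
    """Brute-force visible arc by casting sight lines (verification).

    Mid-circle angles are sampled every ``angle_step_deg`` and card
    points every ``card_step_cm`` along the outer wall; a sight line is
    blocked when the segment's closest approach to the centre lies
    strictly inside the inner wall.
    """
    if convention not in CONVENTIONS:
        raise ParameterError(f"unknown visibility convention {convention!r}")
    r = geom.radius_inner
    card = geom.card_arc
    n_phi = int(round(360.0 / angle_step_deg))
    phis = np.radians(geom.card_angle_deg
                      + angle_step_deg * np.arange(n_phi))
    n_q = max(2, int(np.ceil(geom.card_width_cm / card_step_cm)) + 1)
    qa = np.radians(np.linspace(card.lo, card.hi, n_q))
    qx = geom.radius_outer * np.cos(qa)
    qy = geom.radius_outer * np.sin(qa)
    px = geom.radius_mid * np.cos(phis)
    py = geom.radius_mid * np.sin(phis)
    # segment P->Q vs inner circle, vectorized over (phi, card point)
    dx = qx[None, :] - px[:, None]
    dy = qy[None, :] - py[:, None]
    seg2 = dx * dx + dy * dy
    # parameter of the foot of the perpendicular from the origin
    tpar = -(px[:, None] * dx + py[:, None] * dy) / np.maximum(seg2, 1e-12)
    foot_inside = (tpar > 0.0) & (tpar < 1.0)
    fx = px[:, None] + tpar * dx
    fy = py[:, None] + tpar * dy
    blocked = foot_inside & (fx * fx + fy * fy < r * r)
    visible = (~blocked).any(axis=1) if convention == "any-point" \
        else (~blocked).all(axis=1)
    extent = visible.sum() * angle_step_deg
    return Arc(geom.card_angle_deg, min(float(extent), 360.0))


@dataclass
class RegionPartition:
    """Visible-cue and non-visible-cue regions with the buffer excluded.

    Both regions have the same angular extent by construction; the
    leftover buffer (split between the two boundaries) is excluded from
    region analyses.
    """

    visible: Arc
    nonvisible: Arc
    visible_arc_deg: float         # raw visible arc before trimming
    buffer_deg: float

    def __post_init__(self) -> None:
        if abs(self.visible.extent_deg - self.nonvisible.extent_deg) > 1e-9:
            raise ParameterError("regions must have equal extents")
        gap = abs(_circdiff(np.array([self.nonvisible.center_deg]),
                            self.visible.center_deg)[0])
        if self.visible.extent_deg > gap:
            raise ParameterError("regions overlap")

    def to_dict(self) -> dict:
        return {
            "visible": {"center_deg": self.visible.center_deg,
                        "extent_deg": self.visible.extent_deg},
            "nonvisible": {"center_deg": self.nonvisible.center_deg,
                           "extent_deg": self.nonvisible.extent_deg},
            "visible_arc_deg": self.visible_arc_deg,
            "buffer_deg": self.buffer_deg,
        }


def region_partition(geom: Optional[TrackGeometry] = None,
                     visible: Optional[Arc] = None,
                     convention: str = "any-point") -> RegionPartition:
    """Equal-sized visible and non-visible regions around the card.

    The visible region is centred on the card, the non-visible region
    diametrically opposite; both are trimmed to the smaller of the
    visible and non-visible arcs so their extents match, and the
    remaining buffer is excluded (e.g. a 160° visible arc gives two
    160° regions with a 40° buffer split in two).
    """
    if visible is None:
        if geom is None:
            raise ParameterError("need a TrackGeometry or a visible Arc")
        visible = visible_arc(geom, convention)
    extent = min(visible.extent_deg, 360.0 - visible.extent_deg)
    return RegionPartition(
        visible=Arc(visible.center_deg, extent),
        nonvisible=Arc(visible.center_deg + 180.0, extent),
        visible_arc_deg=visible.extent_deg,
        buffer_deg=360.0 - 2.0 * extent)


# ---------------------------------------------------------------------------
# region-wise firing stability and field density
# ---------------------------------------------------------------------------

def track_angles(traj: Trajectory) -> np.ndarray:
    """Track angle (degrees, room-anchored) of every tracking sample."""
    return np.degrees(np.arctan2(traj.y1, traj.x1))


def region_stability(spikes: SpikeTrain,
                     traj: Trajectory,
                     series: CumulativeDistanceSeries,
                     partition: RegionPartition,
                     bin_width: float = 10.0) -> Tuple[float, float]:
    """First-peak autocorrelation of the path-integrated profile in each
    region: (r_visible, r_nonvisible).

    Samples (and their spikes) outside a region are masked before
    linearization. A region whose restricted profile spans fewer than
    two firing periods, or has no autocorrelation peak, raises
    InsufficientDataError (the cell is skipped).
    """
    from .coding import autocorrelation_1d

    ang = track_angles(traj)
    out = []
    for name, region in (("visible", partition.visible),
                         ("nonvisible", partition.nonvisible)):
        mask = region.contains(ang)
        if mask.sum() < 2:
            raise InsufficientDataError(f"no samples in {name} region")
        prof = linearize_activity(spikes, series, "path_integrated",
                                  bin_width, sample_mask=mask)
        try:
            ac = autocorrelation_1d(prof)
        except InputError as exc:
            raise InsufficientDataError(
                f"{name} region: {exc}") from None
        if ac.peak_values.size == 0:
            raise InsufficientDataError(
                f"{name} region: no autocorrelation peak")
        period = ac.first_peak_lag
        occupied_extent = prof.occupied.sum() * prof.bin_width
        if occupied_extent < 2.0 * period:
            raise InsufficientDataError(
                f"{name} region covers fewer than two firing periods")
        out.append(float(ac.peak_values[0]))
    return out[0], out[1]


def stability_paired_test(pairs: Sequence[Tuple[float, float]]
                          ) -> Tuple[float, float]:
    """Paired t-test on Fisher-Z-transformed (visible, non-visible) pairs."""
    from .coding import fisher_z

    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InputError("need at least two (r_visible, r_nonvisible) pairs")
    za = np.array([fisher_z(r) for r in arr[:, 0]])
    zb = np.array([fisher_z(r) for r in arr[:, 1]])
    ok = np.isfinite(za) & np.isfinite(zb)
    if ok.sum() < 2:
        raise InsufficientDataError("fewer than two finite pairs")
    t, p = stats.ttest_rel(za[ok], zb[ok])
    return float(t), float(p)


def track_position_profile(spikes: SpikeTrain, traj: Trajectory,
                           bin_width: float = 10.0,
                           radius: float = 75.0) -> LinearizedActivity:
    """Firing profile on the room-anchored track position axis.

    Track position is the signed arc coordinate folded to one
    circumference (cm along the nominal outer circle, clockwise
    positive), identical across sessions of the same enclosure — the
    axis used for cross-session (light/dark) comparisons and for field
    angular centroids.
    """
    C = 2.0 * np.pi * radius
    n = max(1, int(round(C / bin_width)))
    edges = np.linspace(0.0, C, n + 1)
    pos = np.mod(-radius * np.radians(track_angles(traj)), C)
    sx = np.interp(spikes.times, traj.t, traj.x1)
    sy = np.interp(spikes.times, traj.t, traj.y1)
    spos = np.mod(-radius * np.arctan2(sy, sx), C)
    occ, _ = np.histogram(pos, bins=edges)
    counts, _ = np.histogram(spos, bins=edges)
    return LinearizedActivity(frame="allocentric", bin_width=C / n,
                              edges=edges, counts=counts.astype(float),
                              occupancy=occ.astype(float) * traj.dt)


def _position_to_angle(pos: np.ndarray, radius: float) -> np.ndarray:
    """Inverse of the track-position fold: position (cm) -> degrees."""
    return np.degrees(-np.asarray(pos, dtype=float) / radius) % 360.0


def field_angles(spikes: SpikeTrain, traj: Trajectory,
                 bin_width: float = 10.0, radius: float = 75.0,
                 threshold_frac: float = 0.30,
                 min_pixels: Optional[int] = None) -> np.ndarray:
    """Occupancy-weighted angular centroid (degrees) of each firing field.

    Fields are connected regions of the track-position profile above
    ``threshold_frac`` of the peak; the profile is rotated so its
    minimum sits at the fold boundary, letting fields wrap around 0°.
    """
    prof = track_position_profile(spikes, traj, bin_width, radius)
    rate = np.nan_to_num(prof.rate, nan=0.0)
    occ = prof.occupancy
    if rate.max() <= 0:
        return np.empty(0)
    from .maps import detect_fields

    rot = int(np.argmin(rate))
    rolled = np.roll(rate, -rot)
    centers = np.roll(prof.centers, -rot)
    occ_rolled = np.roll(occ, -rot)
    fs = detect_fields(rolled, threshold_frac=threshold_frac,
                       min_pixels=min_pixels)
    angles = []
    for f in fs.fields:
        idx = f.indices
        w = occ_rolled[idx]
        if w.sum() <= 0:
            w = np.ones(idx.size)
        # circular mean of the member-bin angles, occupancy-weighted
        a = np.radians(_position_to_angle(centers[idx], radius))
        angles.append(float(np.degrees(np.arctan2(
            np.sum(w * np.sin(a)), np.sum(w * np.cos(a)))) % 360.0))
    return np.asarray(angles)


@dataclass
class FieldDensity:
    """Field counts by region with the chi-square test against 50:50."""

    n_visible: int
    n_nonvisible: int
    n_excluded: int            # fields falling in the buffer
    chi2: float
    p: float


def field_density_by_region(angles_deg: Sequence[float],
                            partition: RegionPartition) -> FieldDensity:
    """Count field centroids per region and test against a 50:50 split.

    ``angles_deg`` are field angular centroids (e.g. from
    :func:`field_angles`); fields in the buffer are excluded. With no
    field in either region the cell is skipped (InsufficientDataError).
    """
    ang = np.asarray(angles_deg, dtype=float)
    if ang.size == 0:
        raise InsufficientDataError("zero fields: cell skipped")
    in_vis = partition.visible.contains(ang)
    in_non = partition.nonvisible.contains(ang)
    nv = int(in_vis.sum())
    nn = int(in_non.sum())
    if nv + nn == 0:
        raise InsufficientDataError("all fields in the buffer: cell skipped")
    chi2, p = stats.chisquare([nv, nn])
    return FieldDensity(n_visible=nv, n_nonvisible=nn,
                        n_excluded=int(ang.size - nv - nn),
                        chi2=float(chi2), p=float(p))


# ---------------------------------------------------------------------------
# light/dark comparisons
# ---------------------------------------------------------------------------

def profile_correlation(a: LinearizedActivity,
                        b: LinearizedActivity) -> float:
    """Pearson correlation of two profiles over mutually occupied bins."""
    if a.counts.size != b.counts.size or a.bin_width != b.bin_width:
        raise ParameterError("profiles must share the same binning")
    mask = a.occupied & b.occupied
    if mask.sum() < MIN_OVERLAP_PROFILE:
        raise InsufficientDataError(
            f"fewer than {MIN_OVERLAP_PROFILE} mutually occupied bins")
    ra = a.rate[mask]
    rb = b.rate[mask]
    if np.std(ra) == 0 or np.std(rb) == 0:
        raise InputError("constant profile: correlation undefined")
    return float(np.corrcoef(ra, rb)[0, 1])


@dataclass
class LightDarkResult:
    r_light_light: float
    r_light_dark: float        # Fisher-Z mean of the two light-dark values


def light_dark_comparison(light1, dark, light2,
                          bin_width: float = 10.0,
                          radius: float = 75.0) -> LightDarkResult:
    """Cross-session correlations of one cell's track firing.

    Each argument is a ``(spikes, trajectory)`` pair from one session of
    the same cell (two light sessions flanking a dark one). Profiles are
    taken on the room-anchored track position axis so sessions with
    different starting points align; the two light-dark correlations are
    aggregated through Fisher-Z. A missing session (None) skips the cell.
    """
    from .coding import mean_correlation

    sessions = (light1, dark, light2)
    if any(s is None for s in sessions):
        raise InsufficientDataError("missing session: cell skipped")
    profs = [track_position_profile(sp, tr, bin_width, radius)
             for sp, tr in sessions]
    r_ll = profile_correlation(profs[0], profs[2])
    r_ld = mean_correlation([profile_correlation(profs[0], profs[1]),
                             profile_correlation(profs[2], profs[1])])
    return LightDarkResult(r_light_light=r_ll, r_light_dark=r_ld)


def write_partition(partition: RegionPartition, path: str) -> None:
    """Region definitions as JSON (degrees)."""
    with open(path, "w") as fh:
        json.dump(partition.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
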