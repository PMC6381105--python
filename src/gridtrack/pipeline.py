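"""Per-session and study-level orchestration.

``run_session_analysis`` chains the analysis modules over every cell of
a session (maps → linearize → coding → fitmodel → spectral → physio →
cue); per-cell failures are logged and recorded, never fatal.
``run_simulation_study`` generates labelled synthetic cells, classifies
them blind and tabulates the recovery — the package's main validation
surface. Everything is deterministic given (session, config, seed), and
every data-derived threshold is stored next to the flag it gated.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

from . import coding, fitmodel, maps, physio, spectral
from . import cue as cuemod
from .core import (
    GridtrackError,
    ParameterError,
    Session,
    SpikeTrain,
    Trajectory,
)
from .linearize import (
    FRAMES,
    CumulativeDistanceSeries,
    InsufficientDataError,
    linearize_activity,
    segment_laps,
    unwrap_cumulative_angle,
)
from .synth import BehaviorParams, GroundTruth, generate_track_spikes

log = logging.getLogger("gridtrack")

SCHEMA_VERSION = 1
SEED_STRIDE = 1_000_003        # per-cell seed spacing inside a session


def _cell_seed(base: int, index: int) -> int:
    """Deterministic per-cell seed, independent of error paths."""
    return int((base * SEED_STRIDE + 7919 * index + 1) % (2 ** 31 - 1))


def _jsonable(obj):
    """Recursively convert report contents to JSON-serializable types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


# ---------------------------------------------------------------------------
# configuration and report types
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Knobs of a per-session analysis; stored in the report."""

    seed: int = 0
    n_jitter: int = 100              # jitter surrogates per cell per frame
    jitter_percentile: float = 99.0
    jitter_mode: str = "isi"
    alloc_n_perm: int = 1000
    grid_threshold: float = 0.32     # gridness cutoff (shuffle 95th pct)
    hd_threshold: float = 0.24       # HD vector-length cutoff
    fit_frames: Tuple[str, ...] = ("path_integrated",)
    fit_maxiter: int = 200
    slice_test: bool = True
    slice_shifts: Tuple[int, int] = (10, 10)
    slice_percentile: float = 95.0
    bin_width: float = 10.0          # cm, linearized profiles
    field_bin_width: float = 5.0     # cm, field-centroid profiles

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))


@dataclass
class CellReport:
    """Everything computed for one cell, with thresholds and seeds."""

    unit_id: str
    seed: int
    n_spikes: int = 0
    mean_rate: float = float("nan")
    # 2D map metrics
    gridness: float = float("nan")
    is_grid: Optional[bool] = None
    field_spacing_2d: float = float("nan")
    grid_threshold: float = float("nan")
    # coding classification (linearized frames + allocentric)
    coding: Optional[dict] = None
    label: str = "none"
    field_distance_1d: float = float("nan")
    # spike-train model fits, per frame
    fits: Dict[str, dict] = field(default_factory=dict)
    preferred_fit_frame: Optional[str] = None
    # slice discrimination
    slice_score: float = float("nan")
    slice_threshold: float = float("nan")
    slice_rejected: Optional[bool] = None
    # physiology
    speed: Optional[dict] = None
    hd: Optional[dict] = None
    intrinsic: Optional[dict] = None
    # cue / region metrics
    region: Optional[dict] = None
    field_density: Optional[dict] = None
    # stability
    half_stability: Optional[dict] = None
    errors: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))


@dataclass
class SessionReport:
    cells: List[CellReport]
    summary: dict

    def to_dict(self) -> dict:
        return {"schema_version": SCHEMA_VERSION,
                "summary": _jsonable(self.summary),
                "cells": [c.to_dict() for c in self.cells]}


# ---------------------------------------------------------------------------
# per-session analysis
# ---------------------------------------------------------------------------

def _try(report: CellReport, step: str, fn):
    """Run one analysis step; log and record a failure, return None."""
    try:
        return fn()
    except GridtrackError as exc:
        report.errors.append(f"{step}: {exc}")
        log.warning("unit %s, %s failed: %s", report.unit_id, step, exc)
        return None


def pooled_jitter_thresholds(cells: Sequence[Tuple[SpikeTrain, int]],
                             series: CumulativeDistanceSeries,
                             n: int = 100, percentile: float = 99.0,
                             mode: str = "isi") -> Dict[str, float]:
    """Jitter thresholds pooled across cells, one per frame.

    ``cells`` pairs each spike train with its surrogate seed. Cells on
    which the surrogate statistics cannot be computed are skipped.
    """
    pool: Dict[str, list] = {f: [] for f in FRAMES}
    for spikes, seed in cells:
        if spikes.n_spikes < 5:
            continue
        try:
            st = coding.jitter_statistics(spikes, series, n=n, seed=seed,
                                          mode=mode)
        except GridtrackError:
            continue
        for f in FRAMES:
            pool[f].append(st[f])
    out = {}
    for f in FRAMES:
        if not pool[f]:
            raise InsufficientDataError(
                "no cell yielded jitter statistics: cannot set thresholds")
        out[f] = float(np.nanpercentile(np.concatenate(pool[f]), percentile))
    return out


def session_half_stability(spikes: SpikeTrain,
                           series: CumulativeDistanceSeries,
                           bin_width: float = 10.0) -> Tuple[float, float]:
    """First-peak autocorrelation of each temporal session half.

    Either value is NaN (the cell is flagged, not dropped) when that
    half has too few spikes or no autocorrelation peak.
    """
    tmid = 0.5 * (series.t[0] + series.t[-1])
    out = []
    for mask in (series.t < tmid, series.t >= tmid):
        in_half = spikes.times[(spikes.times >= series.t[mask].min())
                               & (spikes.times <= series.t[mask].max())]
        if in_half.size < 5:
            out.append(float("nan"))
            continue
        try:
            prof = linearize_activity(spikes, series, "path_integrated",
                                      bin_width, sample_mask=mask)
            ac = coding.autocorrelation_1d(prof)
            out.append(float(ac.peak_values[0])
                       if ac.peak_values.size else float("nan"))
        except GridtrackError:
            out.append(float("nan"))
    return out[0], out[1]


def _geometry_from_manifest(manifest) -> Optional[cuemod.TrackGeometry]:
    if manifest.enclosure != "track" or not manifest.cue.present:
        return None
    return cuemod.TrackGeometry(
        radius_outer=manifest.radius_outer,
        radius_inner=manifest.radius_outer - manifest.track_width,
        radius_mid=manifest.radius_outer - manifest.track_width / 2.0,
        card_angle_deg=manifest.cue.angle_deg,
        card_width_cm=manifest.cue.width_cm)


def _analyze_cell(spikes: SpikeTrain, traj: Trajectory,
                  series: CumulativeDistanceSeries, C: float,
                  thresholds: Dict[str, float],
                  partition, config: AnalysisConfig,
                  seed: int) -> CellReport:
    rep = CellReport(unit_id=spikes.unit_id, seed=seed)
    rep.n_spikes = spikes.n_spikes
    rep.mean_rate = spikes.n_spikes / max(traj.duration, 1e-9)
    rep.grid_threshold = config.grid_threshold

    def map_metrics():
        rm = maps.compute_rate_map(traj, spikes)
        ac = maps.spatial_autocorrelogram(rm)
        rep.gridness = maps.gridness(ac)
        rep.is_grid = (bool(rep.gridness >= config.grid_threshold)
                       if np.isfinite(rep.gridness) else None)
        rep.field_spacing_2d = maps.field_spacing_2d(ac)
    _try(rep, "maps", map_metrics)

    def classify():
        cls = coding.classify_cell(
            spikes, series, thresholds, C,
            alloc_n_perm=config.alloc_n_perm, seed=seed,
            unit_id=spikes.unit_id)
        rep.coding = dataclasses.asdict(cls)
        rep.label = cls.label
        rep.field_distance_1d = cls.field_distance
    _try(rep, "coding", classify)

    def fit():
        for j, frame in enumerate(config.fit_frames):
            prof = linearize_activity(spikes, series, frame)
            res = fitmodel.fit_cell(prof, seed=_cell_seed(seed, j),
                                    maxiter=config.fit_maxiter)
            obs = fitmodel.observed_profile(prof)
            denom = float(np.sum(obs[prof.occupied] ** 2))
            rep.fits[frame] = {
                "width": res.params.width,
                "first_offset": res.params.first_offset,
                "spacing": res.params.spacing,
                "ssd": res.ssd,
                "relative_ssd": res.ssd / denom if denom > 0 else None,
                "converged": res.converged,
                "seed": res.seed,
            }
        scored = {f: d["relative_ssd"] for f, d in rep.fits.items()
                  if d["relative_ssd"] is not None}
        if scored:
            rep.preferred_fit_frame = min(scored, key=scored.get)
    _try(rep, "fitmodel", fit)

    def slice_disc():
        rep.slice_score = spectral.one_peakness_score(spikes, series)
        if not np.isfinite(rep.field_distance_1d):
            rep.errors.append("spectral: no field distance for the "
                              "idealized lattice; slice test skipped")
            return
        lattice = spectral.idealized_lattice(rep.field_distance_1d)
        null = spectral.fake_track_null(
            lattice, traj, series, n_shifts=config.slice_shifts,
            seed=seed, percentile=config.slice_percentile,
            n_spikes=spikes.n_spikes)
        rep.slice_threshold = null.threshold
        rep.slice_rejected = spectral.slice_test(rep.slice_score, null)
    if config.slice_test:
        _try(rep, "spectral", slice_disc)

    def speed():
        st = physio.speed_tuning(spikes, traj)
        rep.speed = {"r": st.r, "slope": st.slope,
                     "intercept": st.intercept}
    _try(rep, "physio.speed", speed)

    def hd():
        if not traj.has_heading:
            return
        ht = physio.hd_tuning(spikes, traj)
        rep.hd = {"vector_length": ht.vector_length, "pfd": ht.pfd,
                  "is_hd": bool(ht.vector_length >= config.hd_threshold),
                  "threshold": config.hd_threshold}
    _try(rep, "physio.hd", hd)

    def intrinsic():
        freq, index = physio.intrinsic_theta(spikes)
        rep.intrinsic = {"frequency": freq, "theta_index": index}
    _try(rep, "physio.intrinsic", intrinsic)

    def regions():
        if partition is None:
            return
        rv, rn = cuemod.region_stability(spikes, traj, series, partition,
                                         config.bin_width)
        rep.region = {"r_visible": rv, "r_nonvisible": rn}
    _try(rep, "cue.regions", regions)

    def density():
        if partition is None:
            return
        ang = cuemod.field_angles(spikes, traj, config.field_bin_width)
        fd = cuemod.field_density_by_region(ang, partition)
        rep.field_density = dataclasses.asdict(fd)
    _try(rep, "cue.density", density)

    def halves():
        r1, r2 = session_half_stability(spikes, series, config.bin_width)
        rep.half_stability = {"r_first": r1, "r_second": r2,
                              "flagged": bool(not (np.isfinite(r1)
                                                   and np.isfinite(r2)))}
    _try(rep, "half_stability", halves)
    return rep


def run_session_analysis(session: Session,
                         config: Optional[AnalysisConfig] = None
                         ) -> SessionReport:
    """Analyze every cell of a session; one CellReport per cell.

    An invalid session raises before any analysis; per-cell failures are
    recorded in the cell's ``errors`` list and the run continues. The
    result is fully determined by (session, config).
    """
    config = config or AnalysisConfig()
    session.validate()
    m = session.manifest
    traj = session.trajectory
    if m.enclosure != "track":
        raise ParameterError(
            "run_session_analysis expects a track session; use the maps "
            "module directly for arena recordings")
    C = m.circumference
    series = unwrap_cumulative_angle(traj, radius=m.radius_outer)
    seeds = [_cell_seed(config.seed, i) for i in range(len(session.spikes))]
    thresholds = pooled_jitter_thresholds(
        list(zip(session.spikes, seeds)), series,
        n=config.n_jitter, percentile=config.jitter_percentile,
        mode=config.jitter_mode)
    geom = _geometry_from_manifest(m)
    partition = cuemod.region_partition(geom) if geom else None

    cells = [
        _analyze_cell(st, traj, series, C, thresholds, partition, config,
                      seeds[i])
        for i, st in enumerate(session.spikes)
    ]

    lfp_summary = None
    if session.lfp is not None:
        try:
            th = physio.lfp_theta(session.lfp, traj)
            lfp_summary = {"lfp_peak": th.lfp_peak,
                           "speed_slope": th.speed_slope,
                           "speed_r": th.speed_r}
        except GridtrackError as exc:
            lfp_summary = {"error": str(exc)}
            log.warning("LFP theta failed: %s", exc)

    lap = segment_laps(series, C)
    labels = {}
    for c in cells:
        labels[c.label] = labels.get(c.label, 0) + 1
    summary = {
        "condition": m.condition,
        "duration": traj.duration,
        "circumference": C,
        "travelled": float(series.absolute[-1]),
        "net_laps": float(series.signed[-1] / C),
        "n_lap_rows": int(np.unique(lap).size),
        "n_cells": len(cells),
        "labels": labels,
        "jitter_thresholds": thresholds,
        "partition": partition.to_dict() if partition else None,
        "lfp_theta": lfp_summary,
        "config": config.to_dict(),
    }
    return SessionReport(cells=cells, summary=summary)


def write_report(report: SessionReport, out_dir: str) -> str:
    """Write report.json plus a flat cells.csv; returns the JSON path."""
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "report.json")
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    cols = ["unit_id", "n_spikes", "mean_rate", "label",
            "field_distance_1d", "gridness", "field_spacing_2d",
            "slice_score", "slice_rejected", "errors"]
    with open(os.path.join(out_dir, "cells.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for c in report.cells:
            d = c.to_dict()
            row = [d.get(k) for k in cols[:-1]]
            row.append("; ".join(c.errors))
            w.writerow(row)
    return path


# ---------------------------------------------------------------------------
# simulation study
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Generative and analysis settings of a labelled recovery study."""

    classes: Dict[str, int] = field(default_factory=lambda: {
        "allocentric": 50, "path_integrated": 50,
        "travelled": 50, "time": 50})
    duration: float = 600.0
    n_jitter: int = 50
    jitter_percentile: float = 99.0
    jitter_mode: str = "isi"
    alloc_n_perm: int = 200
    alloc_alpha: float = 0.05
    spacing_range: Tuple[float, float] = (100.0, 250.0)   # cm
    time_spacing_range: Tuple[float, float] = (10.0, 30.0)  # s
    width_fraction: float = 1.0 / 15.0    # field sigma / spacing
    peak_rate: float = 8.0                # Hz
    radius_outer: float = 75.0
    mean_speed: float = 7.0               # cm/s, time-averaged

    def __post_init__(self) -> None:
        for model in self.classes:
            if model not in GroundTruth.VALID_MODELS:
                raise ParameterError(f"unknown coding model {model!r}")
            if self.classes[model] < 0:
                raise ParameterError("class counts must be non-negative")

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("spacing_range", "time_spacing_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulationStudyResult:
    """Classification recovery on labelled synthetic cells."""

    classes: Dict[str, int]
    confusion: Dict[str, Dict[str, int]]   # truth -> assigned label -> n
    flag_rates: Dict[str, Dict[str, float]]  # truth -> frame -> fraction
    allocentric_mean_r: Dict[str, float]
    corrected_mean_r: Dict[str, float]
    spacing_errors: Dict[str, List[float]]  # truth -> relative errors
    thresholds: Dict[str, float]
    seed: int
    records: List[dict]

    def __post_init__(self) -> None:
        for truth, n in self.classes.items():
            got = sum(self.confusion.get(truth, {}).values())
            if got != n:
                raise ParameterError(
                    f"confusion row {truth!r} sums to {got}, expected {n}")

    def recovery(self, model: str) -> float:
        """Fraction of a class flagged in its own reference frame."""
        return self.flag_rates[model][model]

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))


def run_simulation_study(config: StudyConfig,
                         seed: int = 0) -> SimulationStudyResult:
    """Generate labelled cells per class, classify them and tabulate.

    Each class gets its own simulated session (same behavioral
    statistics, different seeds); jitter thresholds are pooled across
    all cells per frame, as in a real analysis where the ground truth is
    unknown. Deterministic given (config, seed).
    """
    total = sum(config.classes.values())
    if total == 0:
        raise ParameterError("study has zero cells")
    rng = np.random.default_rng(seed)
    R = config.radius_outer
    C = 2.0 * np.pi * R

    cells = []        # (truth_model, GroundTruth, spikes, series)
    for ci, (model, count) in enumerate(sorted(config.classes.items())):
        tseed = int(rng.integers(0, 2 ** 31 - 1))
        from .synth import simulate_trajectory
        traj = simulate_trajectory(BehaviorParams.track(
            duration=config.duration, radius_outer=R,
            mean_speed=config.mean_speed, seed=tseed))
        series = unwrap_cumulative_angle(traj, radius=R)
        for i in range(count):
            lo, hi = (config.time_spacing_range if model == "time"
                      else config.spacing_range)
            sp = float(rng.uniform(lo, hi))
            gt = GroundTruth(
                coding_model=model, spacing=sp,
                field_width=sp * config.width_fraction,
                first_offset=float(rng.uniform(0, sp)),
                peak_rate=config.peak_rate)
            cseed = int(rng.integers(0, 2 ** 31 - 1))
            spikes = generate_track_spikes(traj, gt, seed=cseed,
                                           circumference=C,
                                           reference_radius=R)
            spikes.unit_id = f"{model}_{i}"
            cells.append((model, gt, spikes, series, cseed))

    thresholds = {}
    pool: Dict[str, list] = {f: [] for f in FRAMES}
    for model, gt, spikes, series, cseed in cells:
        if spikes.n_spikes < 5:
            continue
        try:
            st = coding.jitter_statistics(spikes, series,
                                          n=config.n_jitter, seed=cseed,
                                          mode=config.jitter_mode)
        except GridtrackError:
            continue
        for f in FRAMES:
            pool[f].append(st[f])
    for f in FRAMES:
        if not pool[f]:
            raise InsufficientDataError(
                "no cell yielded jitter statistics")
        thresholds[f] = float(np.nanpercentile(np.concatenate(pool[f]),
                                               config.jitter_percentile))

    confusion: Dict[str, Dict[str, int]] = {
        m: {} for m in config.classes}
    flag_counts: Dict[str, Dict[str, int]] = {
        m: {f: 0 for f in FRAMES} for m in config.classes}
    alloc_r: Dict[str, list] = {m: [] for m in config.classes}
    corr_r: Dict[str, list] = {m: [] for m in config.classes}
    spacing_err: Dict[str, list] = {m: [] for m in config.classes}
    records = []
    for model, gt, spikes, series, cseed in cells:
        cls = coding.classify_cell(spikes, series, thresholds, C,
                                   alloc_n_perm=config.alloc_n_perm,
                                   alloc_alpha=config.alloc_alpha,
                                   seed=cseed, unit_id=spikes.unit_id)
        confusion[model][cls.label] = confusion[model].get(cls.label, 0) + 1
        for f in FRAMES:
            flag_counts[model][f] += int(bool(cls.flags.get(f)))
        if np.isfinite(cls.allocentric_r):
            alloc_r[model].append(cls.allocentric_r)
        if np.isfinite(cls.corrected_r):
            corr_r[model].append(cls.corrected_r)
        if model in FRAMES and np.isfinite(cls.field_distance):
            spacing_err[model].append(
                abs(cls.field_distance - gt.spacing) / gt.spacing)
        records.append({
            "unit_id": spikes.unit_id, "truth": model,
            "true_spacing": gt.spacing, "label": cls.label,
            "flags": dict(cls.flags), "stats": dict(cls.stats),
            "field_distance": cls.field_distance,
            "allocentric_r": cls.allocentric_r,
            "allocentric_p": cls.allocentric_p,
            "corrected_r": cls.corrected_r,
            "seed": cseed,
        })
    flag_rates = {m: {f: flag_counts[m][f] / max(config.classes[m], 1)
                      for f in FRAMES} for m in config.classes}
    return SimulationStudyResult(
        classes=dict(config.classes), confusion=confusion,
        flag_rates=flag_rates,
        allocentric_mean_r={m: float(np.mean(v)) if v else float("nan")
                            for m, v in alloc_r.items()},
        corrected_mean_r={m: float(np.mean(v)) if v else float("nan")
                          for m, v in corr_r.items()},
        spacing_errors={m: list(map(float, v))
                        for m, v in spacing_err.items()},
        thresholds=thresholds, seed=seed, records=records)


# ---------------------------------------------------------------------------
# cross-environment scale comparison
# ---------------------------------------------------------------------------

@dataclass
class ScaleComparison:
    ratios: List[float]        # track field distance / arena spacing
    mean_ratio: float
    sd_ratio: float
    r: float                   # Pearson correlation across paired cells
    p: float
    n: int


def scale_comparison(track_distances: Sequence[float],
                     arena_spacings: Sequence[float]) -> ScaleComparison:
    """Track-to-arena spacing ratios and their cross-cell correlation.

    Pairs with a missing (non-finite) value on either side are skipped;
    at least two complete pairs are required (three for the
    correlation, otherwise r is NaN).
    """
    a = np.asarray(track_distances, dtype=float)
    b = np.asarray(arena_spacings, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("unpaired inputs: lengths differ")
    ok = np.isfinite(a) & np.isfinite(b) & (b > 0)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise InsufficientDataError("fewer than two complete pairs")
    ratios = a / b
    if a.size >= 3 and np.std(a) > 0 and np.std(b) > 0:
        r, p = sstats.pearsonr(a, b)
    else:
        r, p = float("nan"), float("nan")
    return ScaleComparison(ratios=list(map(float, ratios)),
                           mean_ratio=float(np.mean(ratios)),
                           sd_ratio=float(np.std(ratios, ddof=1)),
                           r=float(r), p=float(p), n=int(a.size))
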