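"""Session serialization: plain-text tracking, spike, LFP and manifest files.

All formats are delimited text so sessions stay auditable with standard
tools. Positions are stored to 0.01 cm and times to 1e-4 s; a session
written, loaded and written again reproduces the files byte-identically.

Layout of a session directory::

    manifest.yaml        key-value manifest (geometry, condition, files)
    tracking.csv         t,x1,y1,x2,y2 (header row)
    spikes_<unit>.txt    one ascending spike time per line (s)
    lfp.csv              t,v (optional)
    ground_truth.json    generator parameters (synthetic sessions only)
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Optional

import numpy as np
import yaml

from .core import (
    CueCard,
    LFPSignal,
    LoadError,
    ParameterError,
    Session,
    SessionManifest,
    SpikeTrain,
    Trajectory,
)

TIME_FMT = "%.4f"     # 1e-4 s
POS_FMT = "%.2f"      # 0.01 cm
LFP_FMT = "%.6f"
GROUND_TRUTH_FILE = "ground_truth.json"
MANIFEST_FILE = "manifest.yaml"


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _write_tracking(path: str, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        fh.write("t,x1,y1,x2,y2\n")
        x2 = traj.x2 if traj.has_heading else np.full_like(traj.x1, np.nan)
        y2 = traj.y2 if traj.has_heading else np.full_like(traj.y1, np.nan)
        for row in zip(traj.t, traj.x1, traj.y1, x2, y2):
            fh.write((TIME_FMT + "," + ",".join([POS_FMT] * 4) + "\n") % row)


def _write_spikes(path: str, spikes: SpikeTrain) -> None:
    with open(path, "w") as fh:
        for t in spikes.times:
            fh.write((TIME_FMT + "\n") % t)


def _write_lfp(path: str, lfp: LFPSignal) -> None:
    with open(path, "w") as fh:
        fh.write("t,v\n")
        for t, v in zip(lfp.t, lfp.values):
            fh.write((TIME_FMT + "," + LFP_FMT + "\n") % (t, v))


def _manifest_dict(m: SessionManifest) -> dict:
    return {
        "enclosure": m.enclosure,
        "radius_outer": float(m.radius_outer),
        "track_width": float(m.track_width),
        "condition": m.condition,
        "cue": {
            "angle_deg": float(m.cue.angle_deg),
            "width_cm": float(m.cue.width_cm),
            "present": bool(m.cue.present),
        },
        "tracking_rate": float(m.tracking_rate),
        "lfp_rate": float(m.lfp_rate),
        "tracking_file": m.tracking_file,
        "spike_files": dict(sorted(m.spike_files.items())),
        "lfp_file": m.lfp_file,
    }


def write_session(session: Session, out_dir: str) -> str:
    """Write a session directory; returns the manifest path.

    File names are taken from the manifest (spike files default to
    ``spikes_<unit>.txt``). The session is validated before writing.
    """
    session.validate()
    os.makedirs(out_dir, exist_ok=True)
    m = session.manifest
    if not m.spike_files:
        m.spike_files = {st.unit_id: f"spikes_{st.unit_id}.txt"
                         for st in session.spikes}
    missing = [st.unit_id for st in session.spikes
               if st.unit_id not in m.spike_files]
    if missing:
        raise ParameterError(f"no spike file name for units {missing}")
    _write_tracking(os.path.join(out_dir, m.tracking_file), session.trajectory)
    for st in session.spikes:
        _write_spikes(os.path.join(out_dir, m.spike_files[st.unit_id]), st)
    if session.lfp is not None:
        if m.lfp_file is None:
            m.lfp_file = "lfp.csv"
        _write_lfp(os.path.join(out_dir, m.lfp_file), session.lfp)
    if session.ground_truth is not None:
        gt = {uid: (g.to_dict() if hasattr(g, "to_dict") else dict(g))
              for uid, g in session.ground_truth.items()}
        with open(os.path.join(out_dir, GROUND_TRUTH_FILE), "w") as fh:
            json.dump(gt, fh, indent=2, sort_keys=True)
            fh.write("\n")
    manifest_path = os.path.join(out_dir, MANIFEST_FILE)
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(_manifest_dict(m), fh,
                       default_flow_style=False, sort_keys=True)
    return manifest_path


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _parse_float(token: str, path: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise LoadError(f"{os.path.basename(path)}, line {lineno}: "
                        f"not a number: {token!r}") from None


def _read_tracking(path: str) -> Trajectory:
    if not os.path.exists(path):
        raise LoadError(f"tracking file missing: {path}")
    with open(path) as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != "t,x1,y1,x2,y2":
            raise LoadError(f"{os.path.basename(path)}, line 1: expected "
                            f"header 't,x1,y1,x2,y2', got {header!r}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 5:
                raise LoadError(f"{os.path.basename(path)}, line {lineno}: "
                                f"expected 5 columns, got {len(parts)}")
            rows.append([_parse_float(p, path, lineno) for p in parts])
    if len(rows) < 2:
        raise LoadError(f"{os.path.basename(path)}: fewer than 2 samples")
    arr = np.asarray(rows)
    t = arr[:, 0]
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise LoadError(f"{os.path.basename(path)}, line {int(bad[0]) + 3}: "
                        f"timestamps not strictly increasing at "
                        f"t={t[bad[0] + 1]:.4f}")
    has_heading = np.isfinite(arr[:, 3]).all() and np.isfinite(arr[:, 4]).all()
    return Trajectory(t=t, x1=arr[:, 1], y1=arr[:, 2],
                      x2=arr[:, 3] if has_heading else None,
                      y2=arr[:, 4] if has_heading else None)


def _read_spikes(path: str, unit_id: str) -> SpikeTrain:
    if not os.path.exists(path):
        raise LoadError(f"spike file missing for unit {unit_id!r}: {path}")
    times = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            times.append(_parse_float(line, path, lineno))
    t = np.asarray(times)
    if t.size > 1 and np.any(np.diff(t) < 0):
        j = int(np.nonzero(np.diff(t) < 0)[0][0])
        raise LoadError(f"{os.path.basename(path)}, line {j + 2}: spike "
                        f"times not ascending")
    return SpikeTrain(times=t, unit_id=unit_id)


def _read_lfp(path: str, sample_rate: float) -> LFPSignal:
    if not os.path.exists(path):
        raise LoadError(f"LFP file missing: {path}")
    with open(path) as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != "t,v":
            raise LoadError(f"{os.path.basename(path)}, line 1: expected "
                            f"header 't,v', got {header!r}")
        t, v = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise LoadError(f"{os.path.basename(path)}, line {lineno}: "
                                f"expected 2 columns, got {len(parts)}")
            t.append(_parse_float(parts[0], path, lineno))
            v.append(_parse_float(parts[1], path, lineno))
    if len(t) >= 2:
        step = t[1] - t[0]
        if abs(step - 1.0 / sample_rate) > 2e-4:
            raise LoadError(f"{os.path.basename(path)}: sample step "
                            f"{step:.6f} s inconsistent with manifest rate "
                            f"{sample_rate:g} Hz")
    return LFPSignal(values=np.asarray(v), sample_rate=sample_rate,
                     t0=t[0] if t else 0.0)


def read_manifest(manifest_path: str) -> SessionManifest:
    if not os.path.exists(manifest_path):
        raise LoadError(f"manifest missing: {manifest_path}")
    with open(manifest_path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise LoadError(f"{os.path.basename(manifest_path)}: "
                            f"unparseable manifest ({exc})") from None
    if not isinstance(raw, dict):
        raise LoadError(f"{os.path.basename(manifest_path)}: manifest is "
                        f"not a mapping")
    try:
        cue = CueCard(**raw.get("cue", {}))
        return SessionManifest(
            enclosure=raw.get("enclosure", "track"),
            radius_outer=raw.get("radius_outer", 75.0),
            track_width=raw.get("track_width", 15.0),
            condition=raw.get("condition", "light"),
            cue=cue,
            tracking_rate=raw.get("tracking_rate", 50.0),
            lfp_rate=raw.get("lfp_rate", 1024.0),
            tracking_file=raw.get("tracking_file", "tracking.csv"),
            spike_files=raw.get("spike_files", {}) or {},
            lfp_file=raw.get("lfp_file"),
        )
    except (ParameterError, TypeError) as exc:
        raise LoadError(f"{os.path.basename(manifest_path)}: invalid "
                        f"manifest: {exc}") from None


def load_session(manifest_path: str) -> Session:
    """Load and fully validate a session directory from its manifest.

    Any malformed or inconsistent record raises :class:`LoadError`
    naming the offending file and line (or unit and spike time).
    """
    manifest = read_manifest(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    traj = _read_tracking(os.path.join(base, manifest.tracking_file))
    spikes = [_read_spikes(os.path.join(base, fname), uid)
              for uid, fname in sorted(manifest.spike_files.items())]
    lfp = None
    if manifest.lfp_file:
        lfp = _read_lfp(os.path.join(base, manifest.lfp_file),
                        manifest.lfp_rate)
    ground_truth = None
    gt_path = os.path.join(base, GROUND_TRUTH_FILE)
    if os.path.exists(gt_path):
        from .synth import GroundTruth
        with open(gt_path) as fh:
            raw = json.load(fh)
        ground_truth = {uid: GroundTruth.from_dict(d)
                        for uid, d in raw.items()}
    session = Session(trajectory=traj, spikes=spikes, lfp=lfp,
                      manifest=manifest, ground_truth=ground_truth)
    session.validate()
    return session
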