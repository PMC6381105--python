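# gridtrack

Analysis of grid-cell recordings on circular tracks and open arenas.
The central question the package answers for each recorded cell is
*what coordinate its periodic firing follows*: allocentric position on
the track, path-integrated (signed) distance, total travelled distance,
elapsed time, or a 1D slice through an undistorted 2D firing lattice.
Around that core it provides rate maps and grid scores, lap-by-lap
stability with a field-spacing-aware lap-shift correction, a
three-parameter spike-train model, spatial-spectrum one-peakness tests
against a fake-track lattice null, speed/head-direction/theta
physiology, and cue-card visibility analyses.

## Quick start (CLI)

```bash
# simulate a 600 s track session with a mixed population of 8 cells
gridtrack simulate mysession --n-cells 8 --seed 1 --with-lfp

# check the session directory is well formed
gridtrack validate mysession/manifest.yaml

# full per-cell analysis -> analysis/report.json + analysis/cells.csv
gridtrack analyze mysession/manifest.yaml --out-dir analysis

# labelled simulation-recovery study (the package's validation surface)
gridtrack study --out study.json --seed 0
```

## Quick start (API)

```python
import numpy as np
from gridtrack.synth import BehaviorParams, GroundTruth, simulate_trajectory, generate_track_spikes
from gridtrack.linearize import unwrap_cumulative_angle, linearize_activity, lap_position_matrix
from gridtrack.coding import (autocorrelation_1d, field_distance_from_autocorr,
                              allocentric_correlation, path_integrated_correlation)

R = 75.0                                   # track outer radius, cm
traj = simulate_trajectory(BehaviorParams.track(duration=600.0, seed=0))
gt = GroundTruth(coding_model="path_integrated", spacing=150.0, peak_rate=8.0)
spikes = generate_track_spikes(traj, gt, seed=1, reference_radius=R)

series = unwrap_cumulative_angle(traj, radius=R)        # signed/absolute distance
prof = linearize_activity(spikes, series, "path_integrated")
dist = field_distance_from_autocorr(autocorrelation_1d(prof))   # ~150 cm

lm = lap_position_matrix(spikes, series, 2 * np.pi * R)
print("uncorrected lap correlation:", allocentric_correlation(lm))
print("corrected:", path_integrated_correlation(lm, dist).mean_r)
```

A path-integrating cell looks unstable lap to lap in track coordinates;
re-aligning each lap by the accumulated shift `circumference mod
field_distance` recovers the correlation. A truly track-anchored cell
gains nothing from the correction.

## Modules

| module | contents |
| --- | --- |
| `core` | data types (Trajectory, SpikeTrain, LFPSignal, Session), error hierarchy |
| `sessionio` | session directory format (YAML manifest + CSV), strict loading |
| `synth` | trajectory and spike-train generators for every coding model, LFP, tuned cells |
| `linearize` | cumulative signed/absolute distance, lap segmentation, linearized profiles |
| `maps` | 2D rate maps, spatial autocorrelograms, gridness, field detection |
| `coding` | 1D autocorrelations, lap-shift correction, jitter nulls, cell classification |
| `fitmodel` | Gaussian spike-train model fits, cross-frame comparison, map reconstruction |
| `spectral` | spatial PSD, one-peakness, fake-track slice null |
| `physio` | speed tuning, head-direction tuning, LFP and intrinsic theta |
| `cue` | cue-card visibility geometry, region stability, light/dark comparisons |
| `pipeline` | per-session orchestration, simulation-recovery studies |

Method conventions and the reasoning behind them are documented in
[docs/methods.md](docs/methods.md).

## Testing

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, which validates the
headline behaviors end to end on synthetic ground truth (classification
recovery on a 200-cell study, lap-shift correction, model-fit recovery,
slice discrimination, oscillation recovery, metric oracles and shuffle
calibration). `python scripts/acceptance.py --seed 1 --out out.json`
computes the same quantities standalone and writes them as JSON.
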