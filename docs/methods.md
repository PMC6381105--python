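# Methods and conventions

This document records the analysis conventions the package implements
and the reasoning behind the non-obvious choices. All quantities are in
cm, seconds and Hz unless stated otherwise.

## Coordinates and frames

The circular track is described by its outer-wall radius `R` (default
75 cm, circumference `C = 2πR ≈ 471.2 cm`). Tracking gives two head
LEDs; the position used for linearization is the first LED.

`linearize.unwrap_cumulative_angle` unwraps the polar angle of the
trajectory and converts it to distance with the *nominal* radius `R`
(not the instantaneous path radius), so distances live on the same axis
as field spacings. Clockwise running is positive. Three reference
frames are derived per sample:

- **path_integrated** — signed cumulative distance `−R·Δθ` (CW and CCW
  cancel);
- **travelled** — absolute cumulative distance (always increasing);
- **time** — elapsed session time.

Allocentric (track-anchored) position is the signed distance folded to
one circumference. Laps are `floor(signed / C)`; the starting sample is
lap 0, so a session that only runs counter-clockwise visits laps −1, 0.

Linearized profiles are spike counts and occupancy on a regular grid of
one frame's coordinate (default 10 cm bins; rates are counts over
occupancy, NaN where unvisited).

## Lap-shift correction

A cell firing every `d` cm of path-integrated distance drifts by
`C mod d` per lap in track coordinates. `coding.path_integrated_correlation`
shifts lap `k` of the lap × position rate matrix by `k · (C mod d)` and
recomputes the mean pairwise lap correlation (Fisher-Z averaged). For a
path-integrating cell the corrected correlation beats the uncorrected
one; when `d` divides `C` exactly the correction is the identity. The
residual uses `(q − floor(q + 1e-9)) · d` with `q = C/d` rather than
`np.mod`, because floating-point `np.mod(C, C/3)` returns the divisor
itself.

`field_distance_from_autocorr` estimates `d` as the first
autocorrelation peak of the path-integrated profile (peaks above the
jitter threshold, falling back to a 0.1 floor).

## Jitter significance tests

Frame periodicity is scored as the mean of the first two
autocorrelation peak values and compared against surrogate spike
trains. Surrogates perturb the inter-spike intervals by a random-sign
magnitude between one fifth of the smallest interval and 0.5 s and
rebuild the train cumulatively; this destroys long-range regularity
while preserving rate and local structure, which is what makes the
percentile threshold discriminative (per-spike displacement of ±0.5 s
at ~10 cm/s moves spikes less than half a profile bin and would leave
the statistic untouched). Surrogate spikes displaced outside the
session window are dropped — clipping them onto the boundary would pile
them into one bin and bias the statistic down. Thresholds are pooled
across all cells of a session per frame (99th percentile by default),
as in an analysis where ground truth is unknown.

The allocentric flag comes from a per-cell lap-rotation permutation
test on the uncorrected lap correlation. Classification labels prefer
"allocentric" when that test fires *and* the uncorrected correlation is
not beaten by the path-integration correction; otherwise the
highest-statistic flagged frame wins. A track-anchored cell is
necessarily also periodic in signed distance, so flags alone cannot
separate the two — the corrected-vs-uncorrected comparison can.

## Spike-train model

`fitmodel` fits a three-parameter model (field width, first offset,
spacing) of an infinite Gaussian train to a linearized profile. The
predicted profile is occupancy-weighted and scaled to the observed
spike count; the observed profile is smoothed with a one-bin Gaussian,
so a noise-free profile of width `w` is matched by a model width
`sqrt(w² + bin²)`. Optimization seeds a deterministic coarse
(spacing, phase) scan into a small number of seeded
differential-evolution runs and keeps the best optimum. The first
offset is identified only modulo the spacing. Cross-frame comparisons
("is this cell better explained by distance or by time?") use the SSD
of the best fit per frame; the preferred frame uses SSD normalised by
the observed sum of squares because the frames have different axis
units.

## Slice test (spatial spectrum)

If track firing were a 1D slice through an undistorted 2D lattice, the
profile would generally be *multi-peaked* in its spatial spectrum
(incommensurate projections of the three lattice axes), whereas genuine
1D periodicity concentrates power at one frequency. The one-peakness
score is the fraction of spectral power in the dominant peak of the
σ = 6-bin-smoothed PSD of the path-integrated profile. Observed scores
are tested against a *fake-track null*: the real path is slid across an
idealized 2D lattice (spacing = track field distance / 1.85, the
empirical track-to-arena spacing ratio) over a grid of phase offsets,
Poisson spikes matched to the observed count are drawn, and the
observed score must exceed the null's 95th percentile to reject the
slice hypothesis. A lattice whose node sits exactly at the track centre
produces a degenerate, nearly periodic slice; generative checks of the
test therefore randomize lattice phase and orientation.

## 2D maps and gridness

Rate maps use 2.5 cm bins with Gaussian smoothing; autocorrelograms are
masked-Pearson at every 2D lag. Gridness is the standard rotational
score (min correlation at 60°/120° minus max at 30°/90°/150°) on an
annulus around the six inner peaks, with a fallback annulus when six
peaks cannot be found (strict mode returns NaN instead). Significance
uses spike-time rotation shuffles (≥20 s), pooled across cells. Note
that a square field of view makes masked-Pearson autocorrelograms
anisotropic at large lags even for radially symmetric maps; analytic
oracles therefore use disc-shaped masks, matching real arena geometry.

## Physiology

Speed tuning is a linear regression of instantaneous rate on running
speed. Head-direction tuning uses the occupancy-normalised tuning
curve; its Rayleigh vector length for a von Mises cell of concentration
κ equals `I1(κ)/I0(κ)` (≈ 0.863 at κ = 4), which anchors the oracle
tests. Preferred-direction stability across sessions uses the V-test
against zero mean difference. LFP theta is the Welch peak in 4–12 Hz;
the frequency-vs-speed slope comes from regressing Hilbert
instantaneous frequency on speed (instantaneous-frequency noise
dominates the small frequency spread, so the slope — not the
correlation — is the calibrated quantity). Intrinsic theta uses the
spike-train autocorrelogram spectrum with a theta-index floor of 5.

## Cue-card geometry

The card hangs on the outer wall; the inner wall occludes it. The
visible arc is closed-form: the limiting sight line is the common
tangent to the inner circle, giving a maximal angular separation of
`arccos(r_in/R_out) + arccos(r_in/R_mid)` between a card border point
and a mid-track point. Two conventions are exposed ("any-point"
default, "whole-card"), and a brute-force ray-cast verifier agrees with
the closed form to < 0.5°. Region analyses trim the visible region
(centred on the card) and the diametrically opposite non-visible region
to equal extents and exclude the leftover buffer. Cross-session
(light/dark) profile correlations and field angular centroids use the
*room-anchored* track position axis — the signed-distance fold brought
to a common origin — because each session's raw path-integrated origin
is its arbitrary starting point. Field centroids are occupancy-weighted
circular means.

## Simulation studies and determinism

`pipeline.run_simulation_study` generates labelled populations (field
spacings uniform in 100–250 cm, time spacings 10–30 s, field σ =
spacing/15, peak rate 8 Hz, 600 s sessions), pools jitter thresholds
across all cells, classifies blind and tabulates confusion matrices,
flag rates and gain comparisons. Everything in the package is
deterministic given (data, config, seed); per-cell seeds are derived
from the session seed with a fixed stride so error paths cannot shift
them. The track-to-arena spacing comparison (`scale_comparison`)
reports per-cell ratios (≈ 1.85 for slice-consistent scales) and their
cross-cell correlation.
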