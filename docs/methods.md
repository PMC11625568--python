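# Methods

`kinegait` implements a single-RGB-D-camera gait-analysis chain of the kind
used to validate depth-camera body tracking against marker-based motion
capture, together with a synthetic gait generator that supplies exact
ground truth for every stage.

## Processing model

**Inputs.** A body-tracking stream is a sequence of ~30 fps frames, each
carrying a timestamp and the 3D positions of named skeletal joints; the
camera's depth axis (z) is also the walking direction, since the subject
walks straight toward the device. Only six joints are consumed: both
ankles (event detection), both hips (CoM proxy), both feet (pass-through).
Positions are converted to meters on read and timestamps re-based to zero.
Frames missing a required joint are dropped before resampling — the
resampler bridges the gaps — and a stream in which more than half the
frames lack a required joint is rejected outright.

**Preprocessing.** Each joint coordinate is interpolated onto a uniform
50 Hz grid with a cubic spline and then low-pass filtered with a
third-order Butterworth at 5 Hz.

* *Spline boundary conditions.* Not-a-knot (the scipy default). A natural
  spline forces zero second derivative at the trial ends and is therefore
  not exact on cubic polynomials; not-a-knot reproduces cubics to machine
  precision, which the test suite verifies (≤ 1e-9).
* *Zero-phase filtering.* The filter is applied forward–backward
  (`filtfilt`, default on), because event *times* feed every temporal
  parameter and a causal filter would bias them all by a fixed group
  delay. The effective magnitude response is then |H(f)|², i.e.
  1/(1 + (f/5 Hz)⁶) squared for the analog prototype; the digital design
  is steeper near Nyquist, so the analytic value is an upper bound in the
  stopband and the tests treat it as such. Edge transients are suppressed
  by `filtfilt`'s default odd reflective padding.

**Stance/swing segmentation.** An ankle is labeled *swing* (1) at sample
i when |depth[i] − depth[i−1]| strictly exceeds 2 cm, else *stance* (0);
the first sample copies the second. On the 50 Hz grid the rule is a 1 m/s
velocity gate. Equality at the threshold counts as stance: stationary is
the conservative reading of an otherwise undefined tie. Label runs shorter
than `min_phase_samples` (3 samples = 60 ms) are merged into the
surrounding phase, shortest run first, until stable — raw per-sample
deltas chatter near the gate under sensor noise. Each 0↔1 transition is a
gait event: 1→0 a stance onset (initial contact), 0→1 a swing onset
(foot off).

**Strides, steps, gating.** A stride joins two consecutive stance onsets
of the same foot (length = |depth difference|, duration = time
difference). A step, under the default *alternating* definition, runs
from a stance onset of one foot to the next stance onset of the other;
this conventional reading makes step ≈ stride/2, consistent with the
relative magnitudes reported for this kind of setup. The literal
single-ankle reading (one foot's swing displacement — numerically a full
stride length) is available via `step_definition="single_ankle"`. Strides
and steps are retained only when both bounding events lie inside the
analysis window of 1.5–4.5 m from the camera, where whole-body tracking
is reliable on a short walkway.

**Parameters.** Eight per-cycle quantities: step length/time, stride
length/time, double support (time within the cycle with both ankles
labeled stance), foot off (own-side stance time as % of the cycle),
walking speed = stride length / stride time, and cadence = 120 / stride
time (two steps per stride, as conventionally printed). Summary tables
default to averaging strides within a trial before pooling across trials
and sides, with the sample (n−1) standard deviation; stride-level pooling
and the population SD are flags.

**CoM excursions.** The camera-side CoM proxy is the hip-joint midpoint;
the marker-side proxy is the midpoint between the ASIS and PSIS marker
midpoints. Per gait cycle, the excursion along each body direction
(medio-lateral, vertical, antero-posterior) is the coordinate's
peak-to-peak range, in mm. Peak-to-peak was chosen over max-deviation-from
-mean because it matches the magnitudes such studies print for lateral
sway (tens of mm); `mode="max_deviation"` is provided. No detrending is
applied by default — the emulated laboratory walk is axis-aligned — but a
per-cycle linear detrend of ML/V is available for oblique walks. The AP
excursion is the body's progression over one cycle (≈ stride length), not
a sway measure.

**Agreement statistics.** Lilliefors normality (parameters estimated;
classic KS behind a flag), two-sided paired t, accuracy = 100% − MAPE,
Pearson r, RMSE, and Bland–Altman with limits of agreement at
mean ± 1.96 × sample SD of the differences, oriented test − reference.
P-values are raw (no multiplicity correction, mirroring standard practice
in these validation studies). Every statistic is cross-checked in the
tests against an independently written naive implementation to 1e-12.

## Synthetic gait generator

The generator is first-class, tested code, not a fixture. Each ankle's
depth alternates stance plateaus with swing advances of one stride length
following a minimum-jerk profile 10s³ − 15s⁴ + 6s⁵; the two sides are
offset so contralateral stance onsets split the cycle according to the
configured step-length ratio (hemiplegic preset: affected/unaffected =
0.8). Double support emerges from duty factors above 0.5. The pelvis
translates toward the camera at the constant mean speed stride/cycle with
a lateral sinusoid at the stride frequency and a vertical sinusoid at
twice it, so the true per-cycle excursions are exactly: AP = stride
length, ML = 2 × lateral amplitude, V = 2 × vertical amplitude. Frames
are sampled at 30 fps with Gaussian timestamp jitter (SD 2 ms) and iid
Gaussian position noise (SD 3 mm per coordinate, a typical body-tracking
jitter magnitude). Identical configurations and seeds are bitwise
reproducible.

Preset central values (healthy: 1.40 m / 1.02 s / duty 0.60 / ML 42 mm /
V 44 mm pk-pk; hemiplegic: 0.76 m / 1.62 s / duty 0.67 / ML 92 mm /
V 28 mm pk-pk) are the literature-scale magnitudes for self-paced healthy
and post-stroke hemiplegic walking on a short walkway. The default depth
window (5.5 → 1.0 m) reflects a short laboratory walkway and fits about
two healthy strides; recovery studies that need six strides per leg widen
`start_depth` (12 m) explicitly, and the generator truncates with a
warning when the requested strides do not fit.

What the generator does **not** emulate: body-tracking outliers and
occlusion dropouts, soft-tissue artifact, curved or oblique walking
paths, arm/trunk kinematics, and the specific noise spectrum of any real
device (noise is iid Gaussian). Passing recovery tests therefore
demonstrates correctness of the analysis chain under controlled
conditions, not field accuracy on human recordings.

## Known limitation: velocity-gate latency

The threshold detector fires only once the ankle moves more than 2 cm per
20 ms sample, i.e. faster than 1 m/s. Any smooth swing trajectory leaves
and re-enters stance at zero velocity, so detection necessarily lags the
true swing onset and anticipates the true stance onset by the time the
ankle spends below the gate. With minimum-jerk transitions this latency
is ~1.5 samples (healthy stance onsets) to ~5.7 samples (hemiplegic swing
onsets, whose peak swing speed is barely 2.7× the gate). Consequences,
all quantified by the acceptance script:

* stride/step lengths and times are essentially exact (the deterministic
  latency cancels between same-kind events);
* absolute event times are biased by the latency; event *precision*
  (dispersion around the deterministic latency) stays within ±1 sample at
  3 mm noise and degrades monotonically with noise;
* stance is symmetrically expanded, inflating foot off by ~8–12
  percentage points and double support by roughly twice the per-boundary
  latency. The direction matches the over-estimation of these two
  parameters that camera-vs-reference validation studies report.

## Numerical choices and degenerate inputs

Ties at the threshold → stance. Fewer than two stance onsets on a side →
no strides for that side, with a warning rather than an error. A
constant-pose stream yields zero events, zero strides and a clean report
(CLI exit code 2, distinct from crash = 1). Identical measured/actual
vectors give t = 0, p = 1 by convention; constant nonzero differences
raise ("infinite t") instead of returning a misleading number. Accuracy
is undefined when a reference value is zero and raises, naming the pair.
Marker CSVs are written with shortest-round-trip float formatting and
read with round-trip parsing, so a write→read cycle is bit-exact.

## Problem sizes

Tests and the acceptance script use 6-stride trials (~250–400 frames),
10-seed averages for stochastic recovery checks, 100 random trajectories
for the segmentation oracle, and n = 1000 for the Bland–Altman coverage
property; the full suite runs in a few seconds on one CPU.
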