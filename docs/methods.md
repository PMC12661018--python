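# Methods

This note documents the models, parameter choices and numerical decisions
behind `thighacc`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Signal model and coordinate convention

A recording is a uniformly sampled triaxial series in g on body-fixed axes
*U* (longitudinal thigh axis, gravity-aligned when standing, positive
toward the knee), *V* (mediolateral) and *W* (anteroposterior, positive
forward). The axis convention is a package choice — inclination and
forward-lean definitions need an unambiguous frame — and is enforced by
the simulator and documented at the I/O boundary. Timestamps are implied
by a uniform grid; clock offset and drift are modelled explicitly in the
sync module rather than via per-sample stamps, which keeps resampling,
feature extraction and chunking simple and exact.

Device emulation is deliberately minimal: saturation clipping at the
dynamic range (±4 g default, matching small wireless thigh sensors).
Quantisation, temperature effects and on-device filtering are not
modelled; the data model assumes raw clipped samples.

## Features

Epoch *i* covers the 2-s window [i, i+2) s, so consecutive windows overlap
by 1 s and a T-second recording yields ⌊T⌋ − 1 epochs. Filtering (4th-order
Butterworth, zero-phase) happens once, upstream of both the mean and the
SD. The 5 Hz default cutoff sits inside the human-movement band and below
the 6.25 Hz Nyquist frequency of 12.5 Hz recordings; zero-phase filtering
is used so features stay time-aligned with annotations (at the cost of the
magnitude response being squared — a sine at the cutoff emerges at 1/2
amplitude, not 1/√2).

Movement intensity is the SD of the filtered vector magnitude about its
window mean. Defining the SD on the magnitude (rather than per-axis) makes
it rotation-invariant, which decouples intensity from mounting errors.

Cadence is the dominant frequency of the longitudinal axis over a centred
4-s context, restricted to 0.3–4 Hz. Two gates decide whether a dominant
frequency exists at all: the spectral peak must exceed 3× the median
in-band power, and at least half the band power must lie within ±0.35 Hz
of the peak. The second gate matters: raw periodograms of broadband
aperiodic movement routinely show peak/median ratios above 3 by chance, so
a peak-height rule alone would assign spurious cadences to irregular
activity. Welch averaging (2-s segments, 50% overlap) stabilises the
estimate; the spectrum is zero-padded so the reported peak is localised
well below the raw bin width (~0.01 Hz accuracy for clean gait).

The SD saturation correction max(0, c₂σ² + c₁σ + c₀) is a device property
with identity default — no published coefficients exist for the supported
sensors, so they are configuration values, and `calibrate_sd_polynomial`
fits them from co-recorded (or simulated) clipped/reference epoch pairs by
quadratic least squares.

## Classifier

The decision tree (see README) evaluates cycle before run so that
high-intensity pedalling is not swallowed by the SD-based run rule. Lying
is merged into sedentary: sit/lie discrimination with a single thigh
sensor is out of scope. "Move" is the active-but-aperiodic residual class,
a transitional state between standing and walking.

None of the threshold constants are canonical; all live in
`ClassifierConfig` with the defaults listed there (σ_stat = 0.1 g,
θ_sit = 45°, σ_run = 0.72 g, f_run = 2.5 Hz, walk band 0.6–2.5 Hz,
θ_cycle = 40°, cycle band 0.3–2 Hz). The `sweep` CLI command exposes the
walk/stairs threshold sensitivity directly.

The walk-vs-stairs split uses the only individually estimated threshold:
the 0.95 quantile of the participant's walking forward lean plus a 2°
offset. The reference set is chosen by a one-round pre-pass that
classifies epochs with the tree under the fallback threshold (25°) and
keeps those labelled *walk*. A broader pre-filter (all active epochs with
walking-band cadence) would admit stairs and cycling epochs and push the
quantile above the stairs lean itself, defeating the threshold; the
pre-pass breaks that circularity without iteration. With fewer than 60
reference epochs the fallback is used and flagged — short recordings give
uncertain individual thresholds, and misclassification of stairs as
walking is the expected failure mode when the threshold lands too high.

Smoothing is a 5-epoch majority filter (centre label wins ties, then
earliest in window) followed by minimum-bout absorption: bouts shorter
than their class minimum (run 2 s, stairs 4 s, cycle 15 s, others 2 s)
are merged into the longer neighbouring bout, earlier neighbour on ties,
shortest bouts first, until stable.

Chunked processing reproduces whole-recording labels exactly: chunks carry
a 4-s sample margin (enough for the 1-s cadence context plus decay of
filter edge transients), the stairs threshold is estimated once globally,
and smoothing runs over the concatenated series.

Daily aggregation counts minutes per behaviour in consecutive 24-h windows
from the recording start; the across-day mean uses complete windows only
and the trailing partial window is reported separately.

## Calibration

**Device autocalibration** exploits the fact that a still accelerometer
must measure exactly 1 g: per-axis gain and offset are fitted by
minimising ‖(v − offset)/gain‖ − 1 over still-epoch mean vectors
(SD < 0.013 g) with damped iterative least squares. The fit needs stills
in at least three directions more than 15° apart; with fewer the problem
is underdetermined and identity parameters are returned with a warning
flag. That gate is necessary but not sufficient — three barely-distinct,
near-coplanar orientations pass it yet constrain the sphere poorly, so
calibration quality ultimately depends on orientation diversity (full
free-living days provide it; a single lab session may not). Temperature
terms are omitted (no temperature channel in the data model).

**Individual calibration** corrects mounting error with a rotation
estimated from upright locomotion. Reference epochs are active, in the
walking cadence band, and with the mean vector near the longitudinal axis
*in either direction* — inclination < 45° or > 135°, the latter so that an
upside-down-mounted sensor is visible to the pre-pass at all. Estimation
is two-stage: (1) if the median longitudinal component is negative, an
upside-down mounting is flagged and corrected by a 180° flip about *W*;
(2) the median direction of epochs within ±10° of the median forward lean
(a relative trim that isolates the dominant gait mode — walking — from
minority stairs-like gait without assuming any absolute angle) is rotated
onto the canonical gait attitude, 20° forward of +U in the sagittal plane.
Mapping onto +U itself would silently subtract the natural gait lean from
every orientation feature and shift all absolute-angle thresholds; using a
canonical lean keeps the classifier's frame intact. The 20° value is the
package's canonical level-walking thigh attitude and is configurable. The
trim assumes walking dominates locomotion time, which holds in free-living
wear; in a session where stair climbing rivals walking the reference
attitude is biased toward stairs.

Order: device autocalibration first, then rotation. Applied as
sample′ = R · ((sample − offset)/gain).

## Synchronisation

Clock error is modelled as t_dev = offset + (1 + drift·10⁻⁶)·t_ref — the
minimal form covering constant offset and constant-rate drift. Heel-drop
groups (deliberate impacts; simulated as biphasic spikes with an 80-ms
positive lobe so they survive resampling) are detected as clusters of ≥3
peaks above 2.5 g on |U| within a 2-s window, matched across devices by
order, and fitted by least squares (exact with two anchors).

Cross-correlation refinement measures, in evenly spaced 120-s windows, the
residual lag of the band-passed (0.5–3 Hz) longitudinal axes after coarse
alignment, then refits the linear clock model on (window centre, lag).
Three safeguards matter in practice: the lag search is bounded to ±0.3 s
because gait is nearly periodic and an unconstrained search can lock onto
a peak one stride period away; window lags with a normalised correlation
peak below 0.3 are discarded (flat or uncorrelated signal); and the
refined model replaces the coarse one only if the lag-fit residual is
smaller than the lags the coarse model left behind. Anchor detection is
quantised to the sample grid (0.04 s at 25 Hz), which limits
anchor-only drift estimates to ~±100 ppm over a 15-min session;
refinement brings terminal misalignment to a few milliseconds.

## Evaluation

Annotations are interval tracks; each 1-s epoch takes the label covering
the majority of it, transitions inherit the majority behaviour, and epochs
whose majority label is "other"/"invisible"/"uncertain" (or with no
coverage) are excluded. Exclusion is pairwise: an epoch excluded by either
series of a comparison is dropped from both. Comparison resolution is the
1-s epoch grid throughout.

Metrics are one-vs-all; classes with zero true instances are omitted
rather than reported as zero. The overall balanced accuracy is the
unweighted mean of per-class recalls. The overall F1 is prevalence-
weighted; the default weights are typical free-living behaviour
proportions over 24 h (sedentary 75.7%, stand 11.2%, move 4.2%,
walk 5.3%, run 0.4%, stairs 0.5%, cycle 2.0%), renormalised over the
classes present, and are configurable. Display rounding is half away from
zero, two decimals for metrics, integer percent for relative biases.
Bland–Altman uses sample SD (n−1) and ±1.96·SD limits; relative bias is
undefined (flagged, not zero) when the reference mean is zero.

## Simulator: what it emulates and what it does not

Each behaviour is gravity projected at a characteristic thigh inclination
(sedentary 75°, stand 10°, move 15°, walk 20°, run 25°, stairs 35°,
cycle 55° forward) with slow per-second angular jitter (2–3° SD), plus a
sinusoid at the behaviour's cadence on U and W (walk 1.8 Hz / 0.35 g,
run 2.8 Hz / 1.2 g, stairs 1.6 Hz / 0.4 g, cycle 1.1 Hz / 0.3 g), plus
Gaussian sensor noise (0.02–0.05 g), then device clipping. Static
noise-free segments have vector magnitude exactly 1 g. "Move" is
generated as bursts of white noise (0.8–1.8 s on, 0.2–0.5 s off, 0.3 g
burst amplitude over a 0.4 residual-activity floor): white bursts have no
spectral line, so the cadence detector correctly reports aperiodic
movement, and the amplitude keeps epoch intensity between standing and
walking — the defaults are chosen to be separable under the documented
thresholds, which is their design intent, since the class boundaries of
"move" are definitional rather than physical. Simulated annotators
perturb boundary times (Gaussian jitter), mislabel epochs independently
at a set rate and mark a fraction uncertain; 1.5% per-rater mislabelling
reproduces the reliability typical of trained video annotators (~97%
agreement, κ ≈ 0.96).

These are sinusoid+gravity constructions, not biomechanical gait models:
no double-support dynamics, impact transients, soft-tissue artefact, or
posture ambiguity (e.g. a leg resting on a pedal). Passing tests therefore
demonstrate that the pipeline's mechanics — features, tree, calibration,
sync, metrics — behave correctly under signals with the documented
statistical structure, *not* that the default thresholds achieve any
particular accuracy on real recordings. Conversely, phenomena that are
purely mechanical — saturation deflating the SD, aliasing-free
downsampling, clock-model recovery, threshold sensitivity of the
walk/stairs split — are faithfully reproduced and quantitatively tested.

## Problem sizes and numerical choices

The validation suite and acceptance script use seven-behaviour scripts of
3 min per behaviour (21 min, ~31 500 samples at 25 Hz), 15-min sync
sessions, and eight 40-s run segments for the saturation sweep — sizes at
which every recovery property is stable across seeds while the whole
suite runs in well under a minute of simulation time. Downsampling uses an
anti-alias low-pass at 0.8× the target Nyquist followed by linear
interpolation onto the target grid (length ⌊(N−1)·f_t/f_s⌋ + 1, no
extrapolation); equal-rate calls return samples unchanged. Sphere-fit
convergence uses a parameter tolerance of 10⁻⁶; rotations are built by
Rodrigues' formula with the degenerate antiparallel case handled by the
explicit 180° flip. Epoch windows are anchored at integer seconds from
the recording start and the trailing partial window is dropped.

## Known limitations

- Sit and lie are not distinguished (single-sensor limitation).
- The SD-correction polynomial is frequency-agnostic; refitting it per
  sampling rate is deliberately out of scope.
- Autocalibration quality depends on still-orientation diversity that the
  gate can only partially verify.
- Individual calibration assumes walking dominates locomotion time.
- The cadence detector reports a single dominant frequency; mixed gait in
  one window (transitions) yields whichever line is stronger.
- Anchor matching is by order, not combinatorial; protocols must keep
  heel-drop groups in the same sequence on all devices.
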