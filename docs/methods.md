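# Methods

This note documents the models and conventions behind `wormcal`: what the
synthetic-data generator simulates and why, how each analysis stage is
defined, the defaults that matter, and what the validation does and does
not establish about real recordings.

## Signal model

Each neuron has a latent activation `a(t) ∈ [0, 1]` that relaxes first-order
toward a state-dependent target:

    da/dt = (u(t − λ) − a) / τ,    τ = τ_on when rising, τ_off when falling

where `u` is `activity_high` in the neuron's preferred states and
`activity_low` otherwise (`forward_high` = RME-like, active in forward;
`backward_high` = RIM-like, active in backward and omega), and `λ` is the
response lag of a downstream neuron (RME preset: 469 ms after the state
signal; RIM preset: 0). Defaults `τ_on = 0.35 s`, `τ_off = 0.7 s` are in the
range of fast GCaMP-family indicators at these imaging rates. The channels
are

    green(t) = G₀ · (1 + α·a(t)) · bleach_g(t) · m(t) + ε_g(t)
    red(t)   = R₀ · bleach_r(t) · m(t) + ε_r(t)

with baselines `G₀ = 120`, `R₀ = 150` counts, gain `α = 2`, a shared
multiplicative motion artifact `m(t) = 1 + A·sin(2πf_a t + φ)` (default
`A = 0.1`, `f_a = 0.7 Hz`) that cancels exactly in `R = green/red`,
optional per-channel exponential photobleaching (off by default), and
additive Gaussian noise (`σ = 3` counts per channel per frame; Poisson
available for rendered stacks).

`suppression_factor` parameterizes the RME preset on the scale the analysis
reports: `activity_low` is derived so that the *steady-state* suppressed/
active fluorescence-ratio quotient equals the factor (0.45 for the
wild-type preset, i.e. a 45% asymptotic ratio change; 0.80 for the
partial-suppression preset; 1.00 — no modulation — for the
suppression-free, tyramine-deficient-like preset). Because bouts are finite
and the indicator relaxes with `τ_off`, the *windowed* event-locked change
is higher than the asymptote (≈ 50–60% at the default bout statistics);
the generator therefore records, per event, the value obtained by applying
the exact analysis windows to the noise-free ratio, and recovery is always
judged against that recorded truth, not against the asymptote.

## Kinematics

The body is built per frame by integrating tangent angles over arc length
(25 points, body length 300 px), which makes the worm exactly inextensible.
The tangent profile is

    ψ(s, t) = φ(t) + π + w_scale·θ_w·sin(2πs/λ_w − Φ(t)) + turn terms

with heading `φ`, wave tangent amplitude `θ_w = 2π·A_w/λ_w` (lateral
amplitude `A_w = 0.08` body lengths, wavelength `λ_w = 0.9`), and a running
wave phase `Φ` that advances head-to-tail during forward frames and
tail-to-head during backward frames at the undulation frequency (0.6 Hz for
both directions; a single frequency keeps the wave phase-continuous through
direction switches, which in turn makes the switch frame identifiable to
the exact frame). The centroid translates at 0.15 body lengths/s along the
heading (forward) or against it (backward) and is stationary during turns.
Gaussian coordinate noise (0.5 px, configurable) models midline-extraction
error; segmentation accuracy is validated on a ladder of this noise.

States alternate forward → backward → (omega) → forward as a semi-Markov
chain with exponential dwells (means 8, 3, 2 s), a hard minimum backward
bout of 2 s and minimum omega bout of 2 s, and omega probability 0.5 after
each reversal (an `escape_config` emulates touch-evoked escape assays:
longer reversals — minimum 6 s, enough undulation cycles to score three or
more body bends — always followed by a turn).

### Omega-turn execution

No kinematic parameters for turn execution are available from the
literature this pipeline targets, so the turn program is the package's own
construction with three scheduled components per event:

- a **concentrated head bend** (tangent step over `s = 0.04…0.14`) that
  ramps up through the last 0.8 s of the reversal, peaks on the frame
  before turn onset — the frame the head-bend angle is scored on — and
  relaxes over the first 30% of the turn (peak magnitude: wild type
  120° ± 10°, shallow preset 50° ± 8°);
- a **whole-body curl** of constant curvature with total tangent turn
  `Θ`, rising over the first 35% of the turn, held through mid-turn, and
  unwound over the last 35%. At the hold the body is a circular arc whose
  head–tail gap is `|2 sin(Θ/2)/Θ|` body lengths, so closure (< 5%) occurs
  for `Θ ∈ [5.98, 6.62]` rad; since the ramp sweeps every depth up to the
  event's peak, an event closes iff its peak `Θ` exceeds 5.98 rad. Drawing
  `Θ ~ N(6.20, 0.22)` (wild type) and `N(6.07, 0.30)` (shallow preset)
  yields closed-turn rates near the 84% / 55% contrast the presets are
  calibrated to;
- a **heading rotation** distributed across the turn's frames (wild type
  160° ± 12°, shallow preset 145° ± 15°), which sets the turning angle
  measured from centroid travel before and after the turn.

The normal undulation fades in proportion to the strongest turn component
and returns as the body straightens: the turn is modeled as its own motor
program, not a superposition on crawling.

## Analysis stages

**ROI tracking** runs on the red (calcium-insensitive) channel: per frame,
the intensity-weighted centroid of the search window (3× the ROI radius,
default radius 6 px) after subtracting the window median and a 3-MAD noise
floor — without the floor, the aggregate of positive-clipped noise pixels
drags the centroid toward the window center. Track quality is the window
peak over its median; more than 3 consecutive frames below 2.0 raises a
tracking-lost error naming the frame. Intensities are disk means minus an
annulus median (1.5–2.5× radius; a global-percentile background is
available). Frames whose background-subtracted red falls below
`max(10⁻⁶, 1% of median red)` are flagged invalid instead of producing
unstable ratios.

**Smoothing** is a centered boxcar whose length in frames is the window in
seconds times the frame rate, rounded to the nearest odd count (0.27 s at
10 fps → 3 frames); at the edges the window shrinks symmetrically, so no
data are fabricated at bout boundaries and the operator stays linear and
shift-equivariant.

**Segmentation.** The per-frame direction statistic is the integer arc
shift maximizing the Pearson correlation between the curvature profiles of
the frames one step before and after (25-point resampling; positive shift =
head-to-tail = forward). Three guards make the call conservative: the peak
correlation must exceed 0.6 (otherwise no coherent profile exists and the
sign of the centroid velocity projected on the tail-to-head axis decides,
if the worm is moving); the peak must beat the zero-shift correlation by
0.05 (a profile that only changes amplitude in place — a growing turn
bend — is a tie, not a direction); and the running label flips only when
the new sign persists over the next 3 frames with no opposing call
(hysteresis). Ties inherit the previous label; runs shorter than 3 frames
are absorbed. Omega turns are recognized after a reversal (backward labels
within 1.5 s) by a sustained (≥ 2 frame) head-bend magnitude above 60°
(measured as 180° minus the interior angle at point 2) with a stationary
centroid, and extend until locomotion resumes; remaining stationary frames
become pauses (centroid speed < 2% body length/s). On noiseless kinematics
this labeling is frame-exact; at the default noise it stays above 95%
agreement with generator truth (typically ≈ 99.5%).

**Event-locked windows** follow the conventions stated in the README. Two
QC rules beyond the bout-length filter matter in practice: the forward
baseline window must lie entirely within forward locomotion (the preceding
forward bout must cover it), and truncated windows are flagged; rejected
events are counted but never averaged.

**Cross-correlation** uses the biased (divide-by-N) estimator on smoothed,
z-scored series at integer-frame lags within ±5 s; the peak is the lag of
maximum `|ccf|`, ties broken toward zero lag, and a positive peak lag means
the first series leads. The sign convention is stated because only a lag
magnitude is conventionally reported. Note that for a pure sinusoid the
anti-phase trough rivals the true peak under this selection rule; real
calcium traces (and the generator's bout-driven signals) have decaying
autocorrelations for which the rule is unambiguous.

**Turn scoring** takes reversal and turn spans (from segmentation or
curated annotations): head-bend angle on the last reversal frame; body
bends as `floor(Z/2)` where `Z` counts alternations of the smoothed
midbody bend signal (angle at point 7, signed by the cross product) between
excursions beyond ±10°; turning angle between mean centroid-displacement
headings over 2-s windows before the reversal and after the turn (2 s spans
about one undulation period, canceling lateral wobble; windows are clipped
to the flanking forward bouts and flagged when too short); closure as the
minimum head–tail distance with a strict 5%-of-body-length threshold.
Classification: no omega unless turning angle > 120° and ≥ 3 bends; closed
versus shallow by the closure flag. The success-rate denominator defaults
to all scored escapes (per-animal scoring convention), with an
omega-attempts-only option.

**Statistics** are thin wrappers over scipy/statsmodels: pooled-variance
two-tailed Student's *t* (Welch optional), one-way ANOVA with Tukey HSD,
pairwise 2×2 χ² without continuity correction (Yates optional) under Holm
or Bonferroni adjustment — both corrections are exposed because both
conventions appear in practice for turn-success proportions.

## Numerical and interface choices

- Arc-length resampling is linear interpolation along the polyline;
  endpoints are preserved exactly and the 13 points sit at arc fractions
  k/12 to machine precision.
- Angles come from `arccos` of clipped normalized dot products: invariant
  under rotation, translation, scaling, and reflection (unsigned).
- All randomness flows from one seed through per-stage, per-neuron spawn
  keys (stable CRC-based neuron streams), so every output is bit-identical
  across runs; pipeline CSVs are written at full float precision (`%.17g`),
  which is what makes the end-to-end run byte-reproducible and the report
  exactly regenerable from saved intermediates.
- Image stacks are multi-page TIFF (green page then red page per
  timepoint) with a JSON sidecar carrying timestamps, render metadata, and
  in-frame ground-truth soma paths; traces and midlines are plain CSV.
- The rendered field of view follows the soma cluster exactly plus ~1 px
  smooth jitter, emulating a tracking microscope's residual error; RIM sits
  at arc position 0.22 versus RME's 0.10 so neighboring blobs stay outside
  each other's search windows at the default radii.

## Validation scope and limitations

Passing tests establish that each estimator recovers the generator's known
truth under the generator's assumptions: sinusoidal undulation with a
single spatial mode, a stereotyped turn program, Gaussian noise, a
stationary baseline, and somas that never leave the field of view. Real
recordings violate several of these — irregular waves and posture changes,
varying depth/focus, bleaching trends, occlusions and coiling during deep
omega turns (where real midline extraction is least reliable), and
inter-animal variability — so quantitative accuracies measured here
(segmentation ≈ 99%, sub-pixel tracking, sub-point ratio-change recovery)
are upper bounds, not field performance. The scoring conventions the
package fixes where the field's verbal definitions are ambiguous — the
heading-based turning angle, the last-reversal-frame head-bend frame, the
5% closure threshold, full-wave bend counting, interior-angle convention
(180° = straight) — are all exposed as parameters, and results should be
reported with those settings. Sizes used throughout the validation
(60–400 s recordings at 10 fps, 128×128 stacks, cohorts of 100 turns) were
chosen as the smallest that give stable statistics for the quantities
measured.
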