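# Methods

## Problem and approach

Pupil diameter is driven by two separable neural systems: the pupillary
light reflex (PLR), a fast brainstem loop (pretectal olivary nucleus →
Edinger-Westphal nucleus) that constricts the pupil within a few hundred
milliseconds of a luminance increase, and the task-evoked pupillary
response (TEPR), a slow dilation mediated by the locus
coeruleus–norepinephrine system that builds over 1–3 s with cognitive
effort. In a virtual-reality headset the two are normally confounded:
scene luminance changes constantly, and the reflex swamps the much smaller
cognitive signal.

The iso-luminant protocol removes the confound at the source. A session
has three phases on a fixed timeline:

1. **PLR validation (60 s).** The whole field alternates dark (RGB 20)
   and bright (RGB 180), three cycles of 10 s per state. This measures
   each participant's reflex dynamics.
2. **Washout and baseline (60 s).** Constant mid-gray (RGB 90); the final
   10 s are the luminance-adapted baseline.
3. **Cognitive load (240 s).** Luminance stays clamped at the mid-gray
   while auditory tasks alternate low load (passive digit listening) and
   high load (1-back mental addition) in an ABBA block order
   (Low-High-High-Low), 45 s blocks with 15 s rests. Any pupil change here
   is, by construction, not reflex-driven.

The gray levels are 0–255 single-channel proxies for relative luminance;
the stimuli are achromatic and no photometric calibration is assumed.

**Phase 3 arithmetic.** Four 45 s blocks with rests strictly *between*
blocks give 180 + 45 = 225 s. The phase is specified as 240 s, so the
default timeline inserts a leading 15 s rest before the first block; the
leading rest is configurable (`ProtocolConfig.leading_rest`). The leading
rest also gives the first block a defined rest→task onset, which the
dilation-velocity search uses.

## Signal processing

Cleaning runs before filtering, in this order:

1. **Artifact detection.** A sample is flagged *zero* when its diameter
   is ≤ 1e-6 mm or missing (the eye-tracker's blink/dropout encoding), and
   both members of an adjacent pair are flagged *velocity* when the raw
   inter-sample change exceeds ±10 mm/s. Raw first differences are used,
   not a smoothed derivative; flagging both endpoints of an offending pair
   is the conservative reading of the pairwise rule.
2. **Dilation** of the mask by 50 ms (inclusive) on each side, in time
   rather than samples because acquisition jitters around the nominal
   90 Hz. Newly flagged samples carry the reason `dilation`.
3. **Linear interpolation** across flagged runs; runs touching the trace
   edges take the nearest valid value.
4. **Data-loss QC.** The flagged fraction is computed on the dilated mask
   (conservative; `PreprocessConfig.loss_after_dilation` switches to the
   raw mask) and sessions above 15 % are marked excluded. Metrics are
   still computed for excluded sessions; exclusion is applied at the
   cohort level.
5. **Uniform resampling** at 90 Hz by linear interpolation, so that
   fixed-coefficient filters are valid on the jittered grid.
6. **Dual-pathway filtering.** Order-4 Butterworth low-pass applied
   forward–backward (`sosfiltfilt`): 4 Hz for the PLR pathway, 0.5 Hz for
   the cognitive pathway. Zero-phase application removes group delay so
   peak-velocity *timing* is comparable across pathways. The cutoffs are
   deliberately asymmetric: 0.5 Hz on the reflex would flatten its peak
   velocity, while 4 Hz on the cognitive signal would pass noise that
   mimics dilation velocity.

Note that zero-phase filtering squares the magnitude response (effective
order 8). For a constriction with a 0.2 s time constant the 4 Hz pathway
passes only ~70 % of the instantaneous peak derivative; measured peak
velocities are therefore filter-bandwidth-limited estimates, bounded above
by the analytic `amplitude/τ`. This is inherent to any 4 Hz low-pass and
is verified against an oracle that filters the closed-form exponential
directly.

## Outcome metrics

From the 4 Hz trace over Phase 1:

* dark/bright means pool all samples labeled dark/bright;
* amplitude (mm) = dark mean − bright mean;
* constriction % = 100 · amplitude / dark mean;
* peak constriction velocity (mm/s) = largest magnitude of negative
  derivative within 1.0 s after any dark→bright transition (the reflex
  completes within a few hundred ms; window configurable).

From the 0.5 Hz trace over Phase 3 (rests excluded):

* low/high means pool all task-block samples;
* difference (mm) = high mean − low mean;
* percent change = 100 · difference / low mean (per-session denominator);
* peak dilation velocity (mm/s) = largest positive derivative within
  5.0 s after each rest→high transition.

Derivatives are central differences on the uniform grid (one-sided at the
edges), exact for affine signals. Peak velocities are per-session maxima
across transitions, not averages. The dissociation statistic is

    velocity ratio = peak constriction velocity / peak dilation velocity,

dimensionless, with values well above 1 indicating that constriction is
reflex-fast while dilation is effort-slow.

`MetricsConfig.settle_skip_s` (default 0 s, i.e. whole-state pooling) can
drop the first part of each state before averaging. With first-order
dynamics the state mean includes the approach transient, which biases the
amplitude low by roughly `amplitude · τ_redilation / T_state` per affected
state (~0.13 mm at defaults). When the goal is recovering the *plateau*
amplitude — as in the simulator-based parameter-recovery tests — a 2 s
settle-skip removes this bias to < 0.01 mm; the default remains
whole-state pooling to match the conventional analysis.

## Cohort statistics

Excluded sessions are dropped; per metric the table reports n, mean, SD
(n−1 denominator), and range. Validation tests: one-sample t (two-sided)
of amplitude and of difference against 0, with one-sample Cohen's
d = (mean − μ₀)/SD = t/√n; Wilcoxon signed-rank of the velocity ratio
against 1, one-sided (greater), via the normal approximation

    z = (W⁺ − n(n+1)/4) / √(n(n+1)(2n+1)/24)

with average ranks for ties, zero differences dropped, and no continuity
correction by default (with all 22 ratios above 1 this gives z = 4.11; the
correction would give 4.09). For n ≤ 16 an exact-enumeration p over all 2ⁿ
sign patterns is available as an oracle; the continuity-corrected
approximation is what matches the inclusive discrete tail, and is compared
against the exact p in tests.

## Synthetic sessions

The simulator provides ground-truthed inputs in place of deposited
recordings. The model is deliberately minimal — the simplest dynamics
consistent with reflex completion in hundreds of milliseconds and
task-evoked dilation over seconds:

* **Luminance pathway:** the diameter tracks a piecewise-constant target
  (dark → baseline, bright → baseline − amplitude, iso → baseline −
  0.5·amplitude) by exact first-order steps, with time constant 0.2 s when
  constricting and 0.4 s when redilating, after a 0.25 s reflex latency.
  The iso-level target is a modeling choice (mid-gray sits between the
  dark and bright targets); no published iso-level diameter exists.
* **Cognitive pathway:** an additive component tracks
  `tepr_amplitude` during high-load blocks and 0 elsewhere with time
  constant `tepr_ramp_s/3` (default 2/3 s), giving a ~95 % rise in 2 s and
  decay during rests.
* **Nuisance terms:** a hippus sinusoid (0.05 mm at 0.15 Hz), independent
  per-eye Gaussian sensor noise (0.02 mm SD), timestamp jitter (0.5 ms SD,
  clipped to keep the grid strictly increasing), and blinks as zero-valued
  gaps in both eyes at Poisson times (0.2 Hz, 100–200 ms), yielding ~5 %
  data loss after mask dilation — under the 15 % exclusion limit.

Ground truth records the plateau amplitude, the analytic peak velocities
(`amplitude/τ` at onset for both pathways), the noiseless TEPR
condition-mean difference, and the injected blink intervals. Cohorts draw
per-session dark baselines U(3.75, 6.80) mm, constriction fractions
U(0.254, 0.411) and TEPR amplitudes U(0.15, 0.80) mm — spanning the
published distribution of healthy adults so simulated summary statistics
are order-of-magnitude comparable (comparability, not equality, is the
contract). Seeding uses `numpy.random.SeedSequence(seed).spawn(n)`, which
is prefix-stable: session *i* is identical whatever the cohort size.

What the simulator does *not* emulate: pupil foreshortening with gaze
angle, saccade-locked transients, slow arousal drift, partial-occlusion
diameter bias around blinks, or asymmetric anisocoria. Passing tests
therefore demonstrate pipeline correctness under the stated model, not
performance on any particular hardware's artifact spectrum.

## Numerical choices and degenerate inputs

* Half-open interval convention: a boundary time belongs to the interval
  it starts, so a transition sample is labeled with the new state.
* Binocular reduction: per-sample mean of the valid eyes (symmetric,
  robust to monocular dropouts); single-eye selection is available. Eye
  openness is stored but does not gate validity.
* Exclusion is strict: loss fraction exactly 0.15 is kept.
* Zero-variance metric vectors make t and d degenerate; the cohort table
  flags the row instead of reporting a statistic. All values equal to the
  Wilcoxon null likewise raise a degenerate-data error.
* Filter preconditions: cutoff must be below Nyquist and the series longer
  than the filtfilt pad length; violations raise typed errors rather than
  propagating scipy's.
* All-flagged traces are unrecoverable and raise rather than silently
  returning an extrapolation.

## Problem sizes

Tests and the acceptance script use full-length 360 s sessions at 90 Hz
(~32,400 samples); simulated cohorts use n = 22 (the published cohort
size) or n = 20 (parameter recovery). A full simulate → analyze → cohort
round trip for 22 sessions takes a few seconds on one CPU.
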