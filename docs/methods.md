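# Methods

This note documents the models, defaults and numerical choices behind
`socgaze`, and what the synthetic-data tests do and do not establish about
recorded data.

## Coordinate frame and data model

All positions are degrees of visual angle, screen-centered, +x rightward,
+y upward; timestamps are trial-relative milliseconds with stimulus onset
at t = 0.  Pixel-coded input is converted per axis as
deg = atan(offset_mm / distance_mm)·180/π using the supplied screen
geometry (resolution, pixel pitch, viewing distance); the conversion is
exactly invertible, and the round-trip error is below 0.01 px everywhere
on screen.  Screen geometry has no universal default and must be supplied
for pixel data.  One monocular gaze channel is carried; samples lost to
blinks or dropout are flagged invalid, never deleted, so stream length is
conserved through I/O round-trips.

## Event detection

Velocity is estimated by central differences of position followed by a
3-sample moving average; acceleration is the central difference of the
smoothed speed.  This differentiator is a deliberate choice — the
detection criteria themselves are thresholds only — and matches common
video-eyetracker parser behaviour while stabilizing the acceleration
trace.

* **Saccade onset**: first sample where speed ≥ 22 °/s *or*
  |acceleration| ≥ 8000 °/s²; **offset**: first subsequent sample where
  both fall below.  The OR-onset convention resolves the ambiguity of a
  bare "velocity and acceleration" criterion pair in the standard
  direction.
* Above-threshold runs separated by < 20 ms merge into one saccade;
  runs touching a stream edge or lacking a finite flanking sample are
  rejected, so every event is bracketed by sub-threshold samples.
* **Blinks** are maximal invalid runs.  A 20 ms margin around each blink
  is excluded from *velocity estimation only* (lid artifacts corrupt the
  derivative); fixation membership is decided on raw validity, so a
  16-sample valid span adjacent to a blink still counts as a fixation.
* **Fixations** are the maximal valid spans left over after removing
  saccades; duration is counted as n_samples × dt, so a span of exactly
  16 samples at 500 Hz is retained at the 32 ms minimum and 15 samples
  (30 ms) is dropped.

## Global-effect statistic

The per-trial deviation is the angle between the first saccade's
displacement vector (start → end, not landing position alone) and the
origin → target vector, signed by which side of the direct path the
endpoint lands on (positive = social side).  Numerically the magnitude is
atan2(|u × v|, u · v), which is stable near collinearity; a zero-length
saccade vector is an error.  Choices on points the task description
leaves open:

* The latency window [70, 500] ms is inclusive at both boundaries.
* "First saccade" means the earliest saccade with onset ≥ 0; anticipatory
  movements starting before stimulus onset are ignored for selection.
* Saccades under 1° amplitude are not eligible as the first saccade
  (microsaccade guard; configurable).
* The 75 % capture rule applies per scramble condition separately, and
  exactly 75 % is included (strict "fewer than" reading).

The statistic is antisymmetric under relabeling social ↔ nonsocial
positions and invariant in magnitude under left–right mirroring; both laws
are property-tested.

## Freeview statistic

AOIs are the exact image rectangles (5.59° × 4.19°), zero padding —
the conservative choice where no margin is defined; image centers default
to ±4.5° so the inner edges are ≈1.7° apart.  Each fixation's full
duration is credited to the AOI containing its centroid (a sample-level
mode exists for sensitivity checks); fixations outside both AOIs count for
neither.  Trials with zero in-AOI time are skipped, not scored 0.5.  The
initial central fixation is kept by default (configurable), since
discarding it is not part of the analysis being reproduced.  The
proportion obeys complement symmetry (p → 1 − p under label swap) and sum
conservation (dwell ≤ trial duration).

## Statistics layer

t statistics, Cohen's d, Pearson r, Steiger's Z and the Cousineau
normalization are computed from their defining formulas; SciPy supplies
only the t and normal distribution functions for p-values.  Cohen's d for
one-sample and paired tests uses the sample SD (n − 1), i.e. d = mean/SD,
so printed means and SDs reconstruct printed d values exactly
(1.433/1.395 = 1.027).  Steiger's Z uses the pooled-correlation form:
with z̄ = atanh(r), r̄ = (r_jk + r_jh)/2,

    ψ = r_kh(1 − 2r̄²) − r̄²(1 − 2r̄² − r_kh²)/2,
    Z = (z_jk − z_jh) · sqrt((n − 3) / (2 − 2ψ/(1 − r̄²)²)),

whose null calibration is pinned by a 2000-replicate simulation test
(rejection rate 5 % ± 1 % at n = 68).  A zero-variance sample off the null
reports an infinite statistic with p = 0 rather than raising.  EQ
correlations are computed on the complete-case subset when scores are
missing.  No multiple-testing correction is applied anywhere; the report
states how many tests it ran.

## Synthetic-data generator

The generator is the test vehicle for the pipeline; its kinematic model is
chosen for plausibility and detectability, not as a scientific claim.

* **Saccades**: minimum-jerk position profiles, duration 2.2·A + 21 ms, so
  peak velocity 1.875·A/T exceeds the 22 °/s threshold for any amplitude
  ≥ 1°.
* **Fixational jitter**: Gaussian noise smoothed on a 20 ms timescale and
  rescaled to 0.05° RMS, keeping sample-to-sample velocities far below
  threshold (white jitter at 500 Hz would trigger false saccades).
* **Global-effect trials**: hold at center for a latency drawn from a
  normal(200, 60) ms truncated to [30, 600] ms — consistent with the short
  latencies characteristic of this paradigm, with enough low-tail mass
  that roughly 1–2 % of trials fall outside the [70, 500] ms window,
  comparable to the exclusion rate the analysis is designed to report —
  then one saccade to the target rotated off-path by the participant bias
  plus N(0, 1°) trial noise, then a landing fixation; 800 ms total.
* **Freeview trials**: a 200–350 ms central fixation, then alternating
  fixations between the AOIs for 5 s.  A per-trial dwell share is drawn
  from Beta(κp, κ(1 − p)) with κ = 50 around the participant proportion p,
  and the in-AOI looking budget is split in exactly that ratio, so the
  expected measured share equals p (verified unbiased to < 0.005 at 300
  trials).  Fixation durations are Dirichlet splits with a 60 ms floor.
* **Cohort structure**: participant dwell proportions and EQ scores are
  linked through a Gaussian copula hitting the target correlations
  (0.278 unscrambled, −0.198 scrambled by default); EQ is rounded to the
  0–80 questionnaire scale around mean 42, SD 12 — typical adult norms,
  chosen once since the source reports no EQ distribution.  Between-
  participant SDs default to the printed condition SDs (1.39°/0.91° for
  deviation, 0.092/0.046 for dwell).  The correlation between the two
  dwell conditions (0.3) is needed by the copula but is not reported
  anywhere; it only affects the dependent-correlation comparison.
* Blinks (rate 0.05/trial, 100–180 ms) are placed away from the primary
  saccade so capture rates stay near the recorded study's.
* `simulate_cohort_summaries` applies the same participant- and
  trial-level noise model but skips sample synthesis, enabling
  Monte-Carlo calibration at hundreds of replicates in seconds.

**What the generator does not emulate**: smooth pursuit, main-sequence
velocity variability, calibration drift, pupil-size artifacts, saccadic
undershoot/corrective saccades, head motion, or any image-content-driven
gaze dynamics.  Passing recovery tests therefore show the *pipeline* is
unbiased and correctly calibrated under realistic noise magnitudes — not
that event detection is robust to every artifact of a physical tracker.

## Problem sizes in tests and the acceptance script

Recovery suites simulate cohorts at the design's sample sizes (67
participants × 80 global-effect trials; 76 × 80 five-second freeview
trials) and accept estimates within 3 Monte-Carlo standard errors of
truth.  The acceptance script averages 10 global-effect and 4 freeview
replicate cohorts and 400 stream-free correlation replicates — sizes
chosen so the whole script completes in about a minute while keeping
Monte-Carlo error a small fraction of each quantity (e.g. ≈0.054° on the
recovered grand-mean deviation).  Type-I calibration uses
2000 replicates (binomial SE ≈ 0.5 %).

## Known limitations

* The ASC-like reader covers the sample/blink/message subset of the
  format, not full EyeLink event records or binary EDF.
* The local-RMS window (10 % of the smaller image dimension,
  non-overlapping tiles) is a convention; the underlying metric is only
  defined up to this choice and the window is configurable.
* Steiger's Z is implemented in its pooled-r form; variants differ in the
  third decimal at these sample sizes.
* The deviation sign convention assumes the image pair is vertical
  (above/below the horizontal meridian), matching the task geometry.
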