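# socgaze

Eye-tracking analysis of **social salience** and **social value** in a
two-task preferential-processing design, for researchers in behavioural and
cognitive neuroscience who record gaze while participants view paired
social and nonsocial reward images.

## The two measures

**Global effect (center-of-gravity) task — orienting / salience.**
A fixation cross jumps 6° of visual angle left or right along the
horizontal meridian; a social and a nonsocial image sit above and below the
new cross location.  Although the images are task-irrelevant, the first
target-directed saccade deviates toward salient distractors.  For each
trial the package computes the signed angle

&nbsp;&nbsp;&nbsp;&nbsp;θ = ∠( saccade displacement vector, origin → target vector )

with θ > 0 when the saccade endpoint falls on the social image's side of
the direct path.  Saccades are parsed from the 500 Hz gaze stream at
22 °/s velocity or 8000 °/s² acceleration; trials whose first saccade
starts before 70 ms or after 500 ms are excluded, and participants
capturing fewer than 75 % of trials in either scramble condition are
dropped.  The participant statistic is the mean θ per condition
(unscrambled and 10-px grid-scrambled controls).

**Preferential looking (freeview) task — engagement / value.**
A social and a nonsocial image (5.59° × 4.19° each) are shown side by side
for 5 s with no task.  Every fixation is credited to the area of interest
containing its centroid, and each trial yields

&nbsp;&nbsp;&nbsp;&nbsp;p = dwell_social / (dwell_social + dwell_nonsocial),

so p = 0.5 means no preference.  Fixations shorter than 32 ms
(16 consecutive samples at 500 Hz) are discarded and blinks are discounted
automatically.

The cohort layer runs one-sample t tests (deviation vs 0; dwell vs 0.5)
with Cohen's *d* = mean/SD, the paired unscrambled-vs-scrambled
comparison, Pearson correlations with trait empathy (Empathy Quotient,
EQ), Steiger's Z for the difference between the two dependent EQ
correlations, and Cousineau within-subject error bars.  All tests are
two-tailed and uncorrected; the report counts the tests it ran.

A synthetic-data module generates full 500 Hz gaze cohorts with known
ground truth (minimum-jerk saccades, smooth fixational jitter, blinks,
Beta-distributed trial-level dwell, a Gaussian copula linking EQ to dwell
bias), so the entire pipeline is testable without any recorded data.
Stimulus-side utilities compute global/local RMS contrast, build
grid-scrambled control mosaics, and run the ratio-vs-1 matching test.

## Worked example

```python
from socgaze import run_pipeline, report_text
from socgaze.simulate import SimulationConfig, simulate_cohort

cfg = SimulationConfig(seed=7, n_participants=12, trials_per_condition=10)
participants, truth = simulate_cohort(cfg)
print(report_text(run_pipeline(participants)))
```

prints

```
Global effect (deviation toward social, deg) — n = 12
  unscrambled: mean = 1.466, sd = 1.190, se = 0.343 (within-subject se = 0.197)
  unscrambled vs 0.0: t(11) = 4.269, p = 0.001324, d = 1.232
  scrambled: mean = 0.021, sd = 0.887, se = 0.256 (within-subject se = 0.197)
  scrambled vs 0.0: t(11) = 0.080, p = 0.9373, d = 0.023
  unscrambled vs scrambled (paired): t(11) = 3.674, p = 0.003663, d = 1.061
  ...
Freeview (social dwell proportion) — n = 12
  unscrambled: mean = 0.540, sd = 0.089, se = 0.026 (within-subject se = 0.012)
  ...
Exclusions (ge): 3 of 240 trials (1.250%), 0.250 per participant; 0 participant(s) removed.
```

The cohort was generated with a true unscrambled deviation of 1.433° and a
true unscrambled dwell proportion of 0.57; the pipeline recovers both
(1.466° and 0.540 at this small n), finds the deviation reliably positive
for intact but not scrambled images, and reports the full exclusion audit.

A command-line front end wraps the same steps:

```bash
socgaze simulate --seed 5 --n-participants 6 --out data/
socgaze run --data data/ --out report/
socgaze ingest recording.asc --format asc
socgaze stimmatch --ratings ratings.csv
```

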