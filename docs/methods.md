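# Methods

## Coordinate and session conventions

All horizontal positions are dimensionless fractions of screen width in
[0, 1]. The published summary tables label movement error and movement
variation "% of screen width" while printing values around 0.2–0.3; fractions
match those magnitudes, so fractions are the internal unit and any display
scaling by 100 is left to the caller.

A session is 60 s of contiguous 2 s game events: event *i* appears at
*i* × 2 s, so 30 events tile the minute exactly and each direction label
occurs 15 times. The logger's sampling rate is not specified by the source
instrument, so the simulator and the alignment grid default to 50 Hz, which
resolves movement onset to ±20 ms; paddle motion is modelled as
horizontal-only along the bottom edge. Target horizontal position is held
constant during the 2 s fall. A target is caught when, at its arrival
instant, |paddle − target| ≤ paddle halfwidth + target halfwidth
(defaults 0.05 + 0.04 screen widths).

## Metric definitions and numerical choices

Per-event traces are clipped to [appearance, appearance + 2 s), re-expressed
relative to appearance, and linearly resampled onto a fixed 101-point grid
(50 Hz plus the endpoint). Events whose window holds no samples are flagged
empty and excluded from metric scopes (a truncated recording degrades to
fewer responses with a warning, not an error).

**Onset detection.** The instrument never defines "start of movement", so the
detector is explicit and configurable: the first time the finite-difference
speed exceeds 0.05 screen-widths/s and stays above it for 100 ms. The
threshold is low enough to catch slow deliberate movements and the sustain
window rejects single-sample jitter; both are carried in the analysis config
and logged with results.

**Movement error** is measured at the target's disappearance instant — the
only moment a paddle–target distance is well-defined for a miss — and is
*absent*, not zero, when nothing was missed.

**Movement variation.** The verbal definition of the source instrument sums
the per-grid-point standard deviations across a direction's traces; summed
over 101 points that would be ~30× larger than the printed 0.26–0.32 values,
which match per-point SD magnitudes instead. The default mode therefore
averages the per-point SDs (`mean_sd`); the literal `summed_sd` mode is
retained, and the two differ by exactly the factor 101 on the fixed grid.
Per-point SDs use the n−1 denominator, and columns of identical values are
forced to exactly zero so that "identical traces ⇒ MV = 0" holds without
floating-point dust.

**Averaging scope.** The original description is internally inconsistent
about whether MOT/ME/MV average 5 or 15 responses per direction; this package
averages over *all* available responses in a direction (misses only for ME,
detected onsets only for MOT, with the detected/missed counts reported
alongside).

## The synthetic-data generator

The validation cohort's raw data is not deposited, so the generator is an
explicit test harness, not a behavioural claim. One simulated player is four
parameters: reaction latency ~ Normal(onset_mean, onset_sd) truncated to the
event window; a constant-speed move toward the target; Gaussian endpoint
noise; and a lapse probability of responding not at all. Defaults
(onset 0.9 ± 0.2 s, speed 0.6 widths/s, endpoint noise 0.18 widths,
lapse 0.15) were chosen once so that simulated sessions land inside the
reported study conditions: success rates near 40% (study range 29–59%),
onset means near 0.9 s, miss magnitudes near 0.2 widths. Event schedules
draw targets uniformly; direction labels record which side of the paddle's
projected position the target fell on, with draws constrained to force the
exact 15/15 split.

For cohort-level work there are two generators. `CohortSpec` draws metric
matrices directly from the two-way random-effects model
y_ij = μ + s_i + o_j + e_ij, so the population ICC
σ²s/(σ²s+σ²o+σ²e) is exact by construction — this is the ground truth used
for estimator-recovery checks. `ResponderPopulation` instead draws one
parameter set per simulated child (held fixed across both occasions), which
produces realistic session-level cohorts whose between-subject metric SDs
match the reported magnitudes; its ICC is emergent, not specified.

What the generator does **not** emulate: fatigue and learning across a
session, within-movement corrections and overshoot, direction-specific
difficulty (direction labels are semantic tags only), torque/inertia of the
physical objects, and any drift between occasions two weeks apart. Passing
tests therefore demonstrate that the *analysis chain* is correct and
well-calibrated, not that the behavioural model reproduces children's
movements.

## Reliability statistics

ICC form is fixed to Shrout–Fleiss (2,1): single measure, absolute agreement
under the two-way random model — the natural reading of "two-way random
model ICC" with one rating per occasion. Its F = MSR/MSE test is reported on
(n−1), (n−1)(k−1) df. The implementation is the closed-form mean-squares
expression; pingouin's `intraclass_corr` serves as an independent oracle in
the tests only.

The MDC chain is SEM = SD·√(1 − ICC), MDC = z·√2·SEM. The source tables
print MDC without a formula; recomputing all 40 cells shows 28 match
z = 1.65 (90% confidence) with the *occasion-1* SD to ±0.01, and a further
minority match the occasion-2 SD. The default is therefore MDC90 from the
test-1 SD, both choices are switchable (`sd_basis`, `confidence`, with 1.96
for 95%), and `reproduce_mdc` annotates which convention fits each reference
cell rather than forcing one. %MDC uses the occasion-1 group mean and is
banded at the 30% (responsive) and 60% (flagged) cut-offs.

The published reliability tables caption their last column "p-value of the
paired t-test", yet several near-identical occasion means carry tiny
p-values there while the accompanying text reports no significant
between-occasion differences — the column is plausibly the ICC F-test p.
Reliability rows therefore always emit both p-values side by side; no guess
is hard-coded.

Paired t-tests are two-tailed by default (no drift direction is
hypothesized). Pearson validity correlations are one-tailed by default with
the *positive* direction hypothesized (performance expected to covary with
reference-assessment scores), which keeps the null p-value Uniform(0, 1) and
the null star rate at the nominal 5%. Statistical packages commonly print
"Sig. (1-tailed)" in the direction of the observed r instead — starring both
signs at a doubled null rate — and `alternative='observed'` reproduces that
convention when matching published layouts. Shapiro–Wilk normality screening
is delegated to scipy's routine and reported, never re-implemented.

## Problem sizes

The estimator-consistency runs use 2000 replicate 35×2 cohorts (matching the
validation cohort's size), 500 synthesized events for parameter recovery,
2000 replicates for the null-uniformity checks and 400 null validity tables
(6400 cells) for the star-rate calibration; these sizes put Monte-Carlo
standard errors well inside the asserted tolerances while the whole suite
runs in seconds.

## Known limitations

- The ICC(2,1) ANOVA estimator is slightly biased at n = 35 (long-run mean
  ≈ 0.795 at a population ICC of 0.8); the recovery checks assert the
  documented 0.02 band, not unbiasedness.
- The printed reference ICCs themselves cannot be recomputed without the
  undeposited child-level data; only the MDC column is derivable from the
  printed inputs.
- Onset detection floors the onset to the alignment grid (≤ one 20 ms step
  of systematic underestimate at 50 Hz).
- No ICC confidence intervals and no Bland–Altman analysis (not part of the
  reported pipeline).
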