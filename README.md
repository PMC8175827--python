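# cuedex

Computer game-based upper-extremity (CUE) assessment toolkit: session
simulation, dexterity metrics, and test-retest reliability analysis for a
target-catching game controlled by instrumented object manipulation.

## The problem

Children with cerebral palsy are assessed for manual dexterity with
observer-scored instruments (PDMS-2, QUEST). A game-based alternative attaches
a motion sensor to an everyday object (peanut ball, soccer ball, tethered
tennis ball, cone, ring); manipulating the object moves a paddle along the
bottom of a screen, and the child catches targets that appear at random
horizontal positions at the top and fall for 2 s. A 60 s session yields 30
*game events* (15 per movement direction), and the logged paddle trajectory
yields four performance measures per direction:

- **SR** — success rate: percentage of targets caught;
- **MOT** — movement onset time: mean latency from target appearance to the
  detected start of paddle movement (s);
- **ME** — movement error: mean paddle–target distance at the target's
  arrival, over missed events only (fraction of screen width);
- **MV** — movement variation: dispersion of the direction's aligned traces,
  from per-sample-point standard deviations (fraction of screen width).

Before such a tool is used to track therapy, its measures must be shown to be
repeatable. This package implements the full psychometric pipeline:

- **relative reliability** — ICC(2,1), the two-way random-effects,
  single-measure, absolute-agreement intraclass correlation
  `(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`, banded
  high ≥ 0.70, moderate 0.50–0.69, low < 0.50;
- **absolute reliability** — SEM = SD·√(1 − ICC),
  MDC90 = 1.65·√2·SEM, and %MDC against the group mean with 30%/60%
  responsiveness cut-offs;
- **systematic error** — paired t-test between occasions;
- **convergent validity** — one-tailed Pearson correlations against reference
  assessment scores (PDMS-2 Grasp/VMI, QUEST).

Because the original child-level data is not deposited, the package ships a
seeded synthetic-session generator (reaction latency, constant-speed pursuit,
endpoint noise, lapses) and a variance-components cohort generator with a
known population ICC, so every statistic can be exercised against ground
truth. The printed summary statistics of the tool's original validation
cohort (35 children, two occasions two weeks apart) are included as reference
data, and the MDC column of those tables is recomputed from the printed ICCs
and SDs.

## Worked example

Simulate a 35-child cohort (subject-specific responder parameters, two
occasions each) and build the reliability table for the peanut-ball task:

```sh
cuedex --seed 42 --out-dir out report --n-subjects 35 --task peanut_ball
```

prints (also written to `out/reliability_peanut_ball.{csv,txt}`):

```
Task: peanut_ball
Variables     ICC    Mean (SD) T1    Mean (SD) T2     MDC    %MDC    p (t)    p (F)
MOT (RF)    0.752     0.90 (0.12)     0.88 (0.15)    0.15    16.1   0.1181   0.0000
MOT (RB)    0.692     0.91 (0.14)     0.88 (0.15)    0.18    20.0   0.1285   0.0000
SR (RF)     0.407   41.90 (14.69)   41.90 (18.62)   26.39    63.0   1.0000   0.0078
SR (RB)     0.493   41.52 (17.87)   43.62 (16.98)   29.69    71.5   0.4866   0.0012
ME (RF)     0.440     0.26 (0.07)     0.24 (0.06)    0.12    45.5   0.1701   0.0032
ME (RB)     0.500     0.24 (0.06)     0.23 (0.06)    0.10    41.9   0.5662   0.0011
MV (RF)     0.345     0.25 (0.05)     0.25 (0.04)    0.09    33.6   0.6253   0.0212
MV (RB)     0.270     0.26 (0.04)     0.26 (0.04)    0.08    29.7   0.3642   0.0564
```

Each row is one measure × direction (RF/RB = roll forward/backward). The ICC
column is the test-retest agreement across the two occasions; MOT rows here
band "high/moderate" while SR rows band "low-moderate" — event-level catch
randomness dominates a 30-event session, which is also why the success-rate
%MDC exceeds 60% (flagged as weakly responsive), mirroring what the original
validation reported for several tasks. `p (t)` is the paired t-test for
systematic drift between occasions (none here); `p (F)` is the ICC F-test.

The same pipeline is available stepwise (`simulate` → `metrics` →
`reliability` / `validity`) and as library functions
(`simulate_session`, `summarize_session`, `build_reliability_table`,
`build_validity_table`).

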