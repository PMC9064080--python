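# posture-entropy

Regularity analysis of postural sway from force-plate recordings.

Standing still is an active control process: the center of pressure (COP)
under the feet wanders continuously as the nervous system corrects the
body's position. How *regular* that wandering is carries information that
summary sway amplitude does not — highly trained athletes (biathletes,
shooters) tend to produce more repetitive, predictable sway patterns in
their trained stances, while novices confronted with the same task become
more irregular. The standard regularity index for such short, nonstationary
signals is **sample entropy (SampEn)**.

This package implements the complete analysis chain for a three-group,
three-task balance study and a synthetic generator that makes every stage
testable without laboratory data:

1. **forceplate_io** — read/write six-channel recordings (Fx, Fy, Fz, Mx,
   My, Mz at 50 Hz) and compute the COP: `cop_x = -My/Fz`, `cop_y = Mx/Fz`.
2. **preprocessing** — 4th-order zero-phase Butterworth low-pass at 7 Hz on
   the channels, then the COP *increment* (first-difference) series.
3. **entropy** — SampEn of the increment series,

   `SampEn(m, r, N) = -ln(A / B)`

   where `B` counts pairs of length-`m` templates within Chebyshev distance
   `r * SD` of each other (self-matches excluded) and `A` counts those
   still within tolerance at length `m + 1`. Defaults `m = 3`, `r = 0.2`.
   A perfectly repeatable series gives 0; i.i.d. noise approaches the
   maximum resolvable value. A brute-force oracle (`sample_entropy_oracle`)
   recomputes the counts independently for verification.
4. **cohort_stats** — average the three repeats per subject and condition,
   check assumptions (Shapiro-Wilk, Levene, Mauchly), run a two-way mixed
   ANOVA (group between subjects, task within) per sway direction with
   generalized eta squared (η²_G) effect sizes, and Bonferroni-corrected
   pairwise t-tests.
5. **synthetic_data** — MIX(p) signals (a sinusoid whose samples are
   replaced by noise with probability p) integrated into COP paths and
   inverted into six plausible force-plate channels; whole cohorts
   (15 controls / 15 beginners / 8 biathletes × 3 tasks × 3 repeats) with a
   tunable (group, task) → irregularity effect matrix.
6. **pipeline** — one-config orchestration with provenance hashing, plus
   the `posture-entropy` command-line interface.

## Worked example

Generate the default synthetic cohort and analyze it:

```sh
posture-entropy synth --design examples/default_design.yaml --out cohort --seed 42
posture-entropy run --config examples/run.yaml
```

Output (seed 42):

```
Mixed ANOVA, direction AP (groups n={'control': 15, 'beginner': 15, 'biathlete': 8}, alpha=0.05):
  group       F = 9.625; df = 2, 35; p<0.001; eta_G^2 = 0.328 (large)
  task        F = 24.964; df = 2, 70; p<0.001; eta_G^2 = 0.075 (medium)
  group:task  F = 48.444; df = 4, 70; p<0.001; eta_G^2 = 0.238 (large)
Mixed ANOVA, direction ML (groups n={'control': 15, 'beginner': 15, 'biathlete': 8}, alpha=0.05):
  group       F = 8.961; df = 2, 35; p<0.001; eta_G^2 = 0.321 (large)
  task        F = 30.993; df = 2, 70; p<0.001; eta_G^2 = 0.065 (medium)
  group:task  F = 76.264; df = 4, 70; p<0.001; eta_G^2 = 0.255 (large)
Post hoc: 20 significant Bonferroni-adjusted comparison(s).
```

Reading this: in both sway directions the three groups differ (large group
effect), the three tasks differ (medium task effect), and — the interesting
part — the groups *respond to the tasks differently* (large interaction).
The post hocs localize the interaction: no group differences in quiet
standing; in the shooting and aiming tasks the biathletes' sway is
significantly more regular (lower SampEn) than both other groups, while
controls and beginners become more irregular than in quiet standing. That
is exactly the qualitative structure the default effect matrix encodes.

The per-trial SampEn table, ANOVA and post-hoc JSON reports, and
assumption checks are written to the configured output directory, each
stamped with the configuration hash.

Library use mirrors the CLI:

```python
import posture_entropy as pe

design = pe.CohortDesign(seed=42)
recordings, manifest = pe.generate_cohort(design)
result = pe.analyze_recordings(recordings, pe.RunConfig())
print(result.anova["AP"].render())
```

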