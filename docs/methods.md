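# Methods

This note records the scientific and numerical conventions the package
implements, the choices that were genuinely open, and what the synthetic
data can and cannot establish.

## Signal chain

A trial is a 30 s, 50 Hz recording of six force-plate channels. Processing
order is fixed: **filter the channels, then compute COP, then difference**.

* **Filtering.** 4th-order low-pass Butterworth, 7 Hz cutoff, applied
  forward-backward (`sosfiltfilt`) with odd-symmetric padding of length
  3·(order+1). Zero-phase application is the biomechanics norm and avoids
  phase-distorting the increment series; it squares the magnitude response,
  so the effective attenuation in dB doubles. A `zero_phase: false` switch
  gives a single causal pass (with the same odd-padded start-up) for
  sensitivity analysis, as does `filter_target: cop` (filter the COP signal
  instead of the channels).
* **COP.** For a plate with its origin in the top surface,
  `cop_x = -My/Fz`, `cop_y = Mx/Fz` (meters); the vertical moment-arm
  correction is omitted. Samples with |Fz| ≤ 10 N raise an unloaded-plate
  error rather than dividing by near-zero: body weight is two orders of
  magnitude above the guard, so any excursion below it is a data defect.
  The plate y axis is reported as anterior-posterior (AP) and x as
  medio-lateral (ML); `axis_rotation_deg` remaps both for stances rotated
  on the plate (e.g. a side-on shooting stance). Whether axes should be
  body- or plate-relative is a genuine ambiguity in multi-stance protocols;
  plate-relative is the default and the flag is the escape hatch.
* **Increments.** The analyzed series is the first difference of each COP
  component. Differencing removes the nonstationary drift of raw COP and
  is the form in which sway regularity is conventionally assessed here.
  For a 1500-sample trial the increment series has n = 1499.

## Sample entropy

`SampEn(m, r, N) = -ln(A/B)` with template length m = 3 and tolerance
r = 0.2 by default. Conventions, each of which the literature leaves open:

* **Distance**: Chebyshev (max norm), the Richman–Moorman convention.
* **Tolerance radius**: r times the *population* SD (divisor N) of the
  analyzed increment series itself, computed after filtering. The
  tolerance must describe the series actually compared, not a precursor.
* **Similarity**: inclusive (≤ radius). This makes the constant series —
  SD 0, radius 0, all distances 0 — give A = B and SampEn = 0, the correct
  "perfectly repeatable" limit; a strict comparison would make it
  undefined instead.
* **Template indexing**: start indices 0..N−m−1 for both the m and m+1
  counts, so the same template set is used at both lengths and A ≤ B holds
  structurally. Self-matches are excluded; counts are reported as ordered
  pairs.
* **Logarithm**: natural (nats).
* **Degenerate outcomes**: B = 0 raises an error (the statistic does not
  exist); A = 0 returns a +inf sentinel with a warning, because short
  regular series can legitimately produce it, and downstream statistics
  treat it as missing — never as a large number.

The optimized counter is a JIT-compiled pairwise loop with early exit; an
independent brute-force oracle recomputes A and B by explicit pairwise
distance matrices. The two are held to integer-exact agreement in the
tests. Note one property that is often stated loosely: A and B each grow
monotonically with r, but their *ratio* — hence SampEn — is only monotone
in r in expectation; finite noisy series show small inversions, and the
tests check the averaged property.

## Cohort statistics

SampEn per trial and direction is averaged over the (up to three) repeats
per subject and condition, then each direction is analyzed separately with
a two-way mixed ANOVA: group (control / beginner / biathlete; between
subjects, 15/15/8) × task (quiet standing QS / shooting position SP /
aiming at target AT; within subjects).

* **Sums of squares**: the classical weighted split-plot decomposition
  (type II under unbalanced groups). This matches what the common R and
  Python implementations compute, and the package's results are verified
  against `pingouin.mixed_anova` to machine precision in the tests. An
  `ss_type="unweighted"` option recomputes the group SS from unweighted
  cell means with the harmonic mean group size (type-III style) for users
  who want SPSS-convention output; with the default design the difference
  is confined to the group line.
* **Effect size**: generalized eta squared, η²_G = SS_effect /
  (SS_effect + SS_subjects-within-groups + SS_task×subjects) — the form
  appropriate for comparing between- and within-subject effects on one
  scale. Bands: small ≥ 0.01, medium ≥ 0.06, large ≥ 0.14.
* **Assumptions**: Shapiro–Wilk per group×task cell, Levene across groups
  per task, Mauchly sphericity of the task factor (trivially satisfied and
  reported as such with only two tasks). Violations are flagged, not
  fatal; when sphericity is rejected a Greenhouse–Geisser corrected p is
  reported alongside the uncorrected one, which remains primary.
* **Post hocs**: independent two-sample t-tests (pooled variance) between
  groups within each task, paired t-tests between tasks within each group.
  Bonferroni correction over the family of all comparisons within a scope
  and direction (9 and 9 for the full design). Scopes run only when the
  corresponding omnibus effect (or the interaction) is significant at
  α = 0.05; `always=True` bypasses the gate. The family definition is a
  convention choice; per-stratum families would be less conservative.

Cells losing all repeats to missing/+inf SampEn raise an error naming the
subject and task rather than silently shrinking the design.

## Synthetic data

The generator's job is to produce signals of *known, graded* regularity
and cohorts with a *known* effect structure.

* **MIX(p)**: a deterministic sinusoid (period 12 samples, variance-matched
  to the noise) in which each sample is independently replaced by uniform
  noise with probability p. SampEn rises monotonically with p in
  expectation, which is what makes the family a regularity dial.
* **Trials**: the COP *increment* series in each direction is MIX(p); the
  COP path is its cumulative sum, centered and rescaled to a 4 mm SD —
  realistic quiet-stance sway amplitude. Channels come from inverting the
  COP equations around a body-weight vertical force (group-specific masses
  ≈ 75/74/59 kg with subject-level spread, 0.5 % multiplicative Fz noise),
  so `compute_cop` recovers the intended path exactly before filtering.
  Because SampEn is affine-invariant, the rescaling does not alter the
  planted regularity.
* **Effect matrix** (defaults): p = 0.42 for every group in QS; 0.58 for
  control and beginner in SP and AT; 0.30 (SP) and 0.26 (AT) for
  biathletes. A per-subject Gaussian intercept on p (SD 0.13) and a
  per-trial jitter (SD 0.04) supply between- and within-subject
  variability; p is clipped to [0, 1]. These magnitudes were chosen once
  so that the simulated cohorts land in the same effect-size classes a
  real cohort of this kind reports — group η²_G large (≈ 0.3–0.5), task
  medium (≈ 0.06–0.11), interaction large — while the qualitative pattern
  (no group separation in QS; biathletes more regular than both other
  groups in SP/AT; untrained groups more irregular in SP/AT than QS) holds
  essentially always. Bar heights from any particular published figure are
  deliberately *not* calibration targets.
* **Summary-level simulation**: `simulate_sampen_table` draws per-trial
  SampEn values directly from a Gaussian random-intercept model, skipping
  signal synthesis. It is the fast path for Monte Carlo calibration of the
  statistics (hundreds of cohorts in seconds); the signal-level path is
  the fidelity check.

What the synthetic data does **not** emulate: inverted-pendulum sway
dynamics, direction-coupled AP/ML control, fatigue or learning across
repeats, heavy-tailed or subject-specific spectral signatures. Passing
tests therefore establish the correctness and calibration of the
*analysis*, not the physiological realism of MIX sway.

## Problem sizes in the test suite

Monte Carlo sizes are chosen to keep the default suite at desk scale:
type-I calibration uses 500 summary-level null cohorts (rejection rate
asserted within 0.05 ± 0.02); power and the qualitative pattern use 24
full signal-level cohorts (342 trials each through the complete pipeline)
against the ≥ 80 % detection requirement — per-replicate success is
essentially certain at the default effect magnitudes, so the reduced
replicate count does not weaken the check. Oracle equivalence covers 100
series up to N = 2000 across m ∈ {2, 3}, r ∈ {0.15, 0.2, 0.25}.

## Known limitations

* Exact reproduction of any specific laboratory dataset additionally
  requires that vendor's COP sign/offset conventions and knowledge of
  whether its pipeline filtered causally; both are configurable here but
  cannot be guessed.
* The ANOVA is the classical univariate split-plot; no REML mixed models,
  no nonparametric fallback when normality fails (violations are flagged
  for the analyst instead).
* SampEn values on +inf-censored cells are treated as missing; heavy
  censoring would bias cell means and is reported through warnings, not
  corrected.
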