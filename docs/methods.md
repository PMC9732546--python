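# Methods

This document records the analysis model, the simulator, parameter defaults
and their rationale, numerical choices, and known limitations.

## Study model and endpoints

A study is a set of arms; each arm is a set of per-mouse growth curves. A
growth curve is a strictly increasing sequence of measurement days starting
at day 1 (start of treatment) with one tumor volume per day, plus a terminal
status (`alive-at-study-end` or `sacrificed`). Mice leave the study
individually, so arms become ragged over time; all between-arm statistics
are computed on *common measurement days* only.

### Volume

Caliper volume defaults to the as-printed formula `V = (a·b)²/2` with `a`
the longer diameter (mm). The conventional modified-ellipsoid formula
`V = a·b²/2` is available through `AnalysisConfig(volume_convention=
"conventional")`. The default is a deliberate fidelity choice to the
reporting convention the workflow reproduces; with both diameters recorded
the two are interconvertible, and RTV-based endpoints are invariant to any
volume rescaling that is common across days.

### RTV and TGI

`RTV(t) = V(t)/V(1)`, so `RTV(1) = 1` exactly. For each day measured in both
arms with at least `min_evaluable_per_arm` mice per arm (default 2),

```
TGI(t) = 100 − (median RTV_treated(t) / median RTV_control(t)) × 100
```

using the sample median (mean of the two central values for even n). TGI is
flagged *meaningful* only at ≥ 50%. The *optimal* TGI is the maximum over
the evaluable days; ties resolve to the earliest day. Day 1 is always a
common day with TGI exactly 0, so an optimal TGI is never negative.

### Responder classification (RTVV / ORR)

At the evaluation day (configurable; defaults to the last common day of the
treated arm and the control arm),

```
RTVV(mouse) = RTV(mouse) / median RTV_control,   ORR = RTVV − 1
```

A mouse is a responder iff `ORR < −0.5` strictly: RTVV exactly 0.5 is a
non-responder. A mouse sacrificed before the evaluation day contributes its
last recorded RTV and is flagged (`used_last_available`). Responder
percentages are rounded half-up to one decimal. Arms are compared on their
responder/non-responder 2×2 table with the exact Fisher test.

### RTV-fold progression ("survival")

For fold thresholds 2 and 4, a mouse's event time is the **first measurement
day** with `RTV ≥ fold` — no interpolation between measurements. Mice that
never cross are censored at their last measurement day. Kaplan–Meier
estimation and the Mantel–Cox log-rank test are delegated to `lifelines`
(events precede censorings at tied times; hypergeometric variance; no
continuity correction). The fold-4 event time can never precede the fold-2
event time on the same curve.

## Hypothesis tests

### Mann–Whitney U (self-contained)

`U` counts pairs `(x, y)` with `x > y`, plus half of the ties (computed via
midranks). For `m + n ≤ 20` and tie-free data the test is **exact**: the
null distribution of U is built with the standard count recurrence
`N(u; m, n) = N(u − n; m − 1, n) + N(u; m, n − 1)` and the two-sided p-value
is `min(1, 2·min(P(U ≤ u), P(U ≥ u)))`. With ties or larger samples the
tie-corrected normal approximation with a 0.5 continuity correction is used
and a `RuntimeWarning` is emitted; zero variance (all values identical)
yields p = 1 with a warning. The n ≤ 20 switchover keeps exact enumeration
cheap (the full U table for 10 vs 10 has 101 entries) while covering any
realistic PDX arm size.

Exactness has a consequence worth knowing: the test is discrete, so its true
type-I level at nominal 0.05 is below 0.05. For 6 vs 6 the two-sided
rejection region is `U ≤ 5 or U ≥ 31`, giving a true level of
38/924 ≈ 0.041.

### Fisher exact (self-contained)

For a 2×2 table with fixed margins, the two-sided p-value is the sum of
hypergeometric probabilities of all tables (same margins) no more likely
than the observed one — the minimum-likelihood rule. Probabilities are
compared through their exact integer numerators `C(r1, k)·C(r2, c1 − k)`,
so the test involves no floating-point likelihood comparisons; the final
p-value is the exact rational sum converted to float.

## qPCR quantification

Input is one Ct per (sample, gene), with two reference rows per sample:
TBP detected with human-specific and murine-specific assays. Then

```
N_target = 2^(Ct_ref − Ct_target),  Ct_ref = mean(Ct_TBP_human, Ct_TBP_murine)
```

If one reference is missing the other is used alone (flagged). Expression is
normalized to a **basal** scale by dividing by `2^(Ct_ref − 35)`: a target
Ct of 35 maps to basal expression 1 and each cycle below 35 doubles it.
`reference_mode="cohort-median"` replaces the per-sample `Ct_ref` with the
cohort median reference, which is useful when reference variability between
samples should not propagate into expression values.

Undetected targets (Ct ≥ 40 or no amplification) are **floored at basal
expression 1 and flagged** (`below_quantification`) rather than dropped:
flooring keeps the sample in rank-based comparisons as "at or below basal",
which is conservative for down-regulation claims, whereas exclusion would
bias group medians upward. `compare_expression(..., exclude_flagged=True)`
is available when exclusion is explicitly wanted. Group comparisons use the
Mann–Whitney test above; because it is rank-based, p-values are invariant
under any common positive rescaling of expression.

## Synthetic cohort generator

Per mouse, the latent model is exponential growth with a multiplicative
treatment effect `e ∈ [0, 1]` on the growth rate:

```
V(t) = V1 · exp(g_i · (1 − e) · (t − 1))
g_i  = g · exp(σ·Z),  σ = sqrt(ln(1 + cv²)),  Z ~ N(0, 1)
```

so the per-mouse growth rate `g_i` is median-`g` lognormal. Observed volumes
apply median-1 lognormal measurement noise (CV `measurement_noise_cv`) on
days after day 1; **day 1 records the enrollment volume exactly**, because
it is the enrollment measurement itself — this preserves the invariant that
baselines lie inside the enrollment window. Mice are measured on days
1, 8, 15, … and are sacrificed individually the first time the *observed*
volume reaches `sacrifice_threshold`; otherwise they run to `max_followup`.

Defaults and rationale:

| Parameter | Default | Rationale |
|---|---|---|
| `growth_rate` g | 0.025 /day | volume doubling ≈ 28 days, typical of slow-growing PDX models such as chordoma |
| `growth_cv` | 0.3 | moderate between-mouse heterogeneity; keeps null arms overlapping without extreme outliers |
| `measurement_noise_cv` | 0.1 | ~10% caliper repeatability |
| `enrollment_window` | (60, 150) mm³ | typical randomization window |
| `sacrifice_threshold` | 500 mm³ | humane-endpoint proxy |
| `measurement_interval` | 7 days | weekly calipering |
| `max_followup` | 120 days | long enough for fold-4 events in slow models |
| `n_per_arm` | uniform 4–7 | realistic small-cohort arm sizes |

Each mouse gets an independent child generator via
`numpy.random.SeedSequence.spawn`, so studies are reproducible per seed and
adding an arm does not perturb the others' draws. The companion
`simulate_ct_table` generates Ct tables: reference Cts are N(25, 0.5²) per
assay, and a target's Ct is `mean(refs) − log2(expression)` with the
configured per-group log2 shifts plus N(0, noise_sd²) noise, so group shifts
translate exactly into fold changes in the noise-free limit.

What the generator deliberately does **not** emulate: tumor regression
kinetics beyond growth arrest (`e` caps at 1, i.e. flat growth), drug
pharmacokinetics or dosing schedules, non-exponential (e.g. Gompertzian)
growth, measurement dropout other than sacrifice, and correlated noise
across days.

## Numerical and I/O choices

- Exact-test p-values come from integer/rational arithmetic where possible;
  floating point enters only at the final conversion.
- CSV readers use pandas with `float_precision="round_trip"`, and writers
  emit `repr()` of floats, so a write/read cycle reproduces volumes and Cts
  bit for bit.
- Report JSON is written with sorted keys and fixed indentation; combined
  with seeded simulation this makes the whole pipeline byte-deterministic.
- Medians use Python's `statistics.median`; responder percentages use
  `decimal` half-up rounding to one decimal place.

## Limitations

- TGI is a median-based point summary without an interval estimate; inference
  relies on the rank tests and log-rank test.
- Event times are measurement-day resolved (weekly by default), so log-rank
  comparisons inherit that granularity; ties are common by construction.
- The exact Mann–Whitney switches to an asymptotic approximation in the
  presence of any tie, even in small samples, and warns when it does.
- Basal qPCR normalization assumes the Ct-35 ≡ basal-expression anchor is
  meaningful for every assayed gene; it is a convention, not a calibration.
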