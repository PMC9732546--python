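# pdxefficacy

Preclinical efficacy and pharmacodynamics analysis for patient-derived
xenograft (PDX) tumor growth studies, with a matching synthetic-cohort
generator for testing and power exploration.

## Scientific problem

In a PDX efficacy study, tumor fragments are implanted in mice, animals are
enrolled when the tumor reaches a target volume window, randomized to a
vehicle control arm or treatment arms, and calipered on a weekly schedule
until sacrifice (tumor burden) or end of study. The analysis questions are:

- **Does the drug slow growth?** Tumor growth inhibition (TGI) compares
  median relative tumor volumes (RTV) between arms over time.
- **Which individual mice responded?** Per-mouse RTVV/ORR classification
  against the control median.
- **Does the drug delay progression?** Time to an RTV-fold endpoint
  (2× or 4× baseline), analyzed with Kaplan–Meier curves and the
  Mantel–Cox log-rank test.
- **Did the drug hit its target?** Relative qPCR quantification of
  pharmacodynamic markers with dual (human/murine) TBP referencing.

## Core quantities

- Caliper volume: `V = (a × b)² / 2` by default (`a` = length, `b` = width,
  mm), with the conventional `a·b²/2` ellipsoid formula available via
  configuration.
- Relative tumor volume: `RTV(t) = V(t) / V(day 1)`; day 1 is the start of
  treatment, so `RTV(1) = 1` exactly.
- `TGI(t) = 100 − (median RTV_treated / median RTV_control) × 100`, reported
  per common measurement day; a TGI is called *biologically meaningful* only
  when it reaches 50%. The *optimal* TGI is the maximum over the study.
- `RTVV = RTV(mouse) / median RTV_control` at end of treatment;
  `ORR = RTVV − 1`; a mouse is a responder iff `ORR < −0.5` **strictly**.
- Group comparisons use a self-contained exact two-sided Mann–Whitney U test
  (exact enumeration up to 20 animals, tie-corrected normal approximation
  beyond) and the exact two-sided Fisher test for responder tables.
- qPCR: `N_target = 2^(Ct_ref − Ct_target)` with `Ct_ref` the mean of human
  and murine TBP; values are normalized so target Ct 35 ≡ basal expression 1.

See `docs/methods.md` for the full model, defaults, and numerical choices.

## Worked example

```python
from pdxefficacy import AnalysisConfig, SimConfig, simulate_study
from pdxefficacy.pipeline import run_efficacy, summarize

study = simulate_study(SimConfig(), {"control": 0.0, "drug": 0.75}, seed=7)
report = run_efficacy(study, AnalysisConfig(), seed=7)
print(summarize(report))
```

prints:

```
PDX efficacy report
control arm: control

arm drug:
  optimal TGI 68.3% at day 50 -- meaningful (TGI >= 50%)
  Mann-Whitney on individual RTVs at day 50: U=0, p=0.00253 (exact)
  responders (ORR < -0.5): 7/7 (100.0%) at day 57
  RTVx2 progression, log-rank vs control: chi2=13.176, p=0.000284
  RTVx4 progression, log-rank vs control: chi2=8.304, p=0.00395
```

The `examples/` directory has one short script per capability: cohort
simulation, efficacy analysis, responder classification, RTV-fold survival,
and qPCR quantification. Each prints the numbers it computes with a one-line
interpretation.

## Command line

A thin CLI wraps the pipeline:

```sh
pdxefficacy simulate --seed 5 --arms "control=0,drug=0.75" \
    --out-measurements meas.csv --out-ct ct.csv
pdxefficacy efficacy --measurements meas.csv --out report/
pdxefficacy qpcr --ct ct.csv --out expression.csv
pdxefficacy report --report-dir report/
```

Exit codes: 0 success, 2 invalid input, 3 analysis not evaluable.

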