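# metspath

Recursive path analysis of metabolic-syndrome (MetS) components in adult
cohorts: which of the five harmonised diagnostic components — waist
circumference (WC), triglycerides (TG), HDL-cholesterol, blood pressure
(SBP/DBP) and fasting glucose (FG) — carries the most weight in a subject's
syndrome status, and how age and body composition act on the components
upstream.

The package is aimed at biostatisticians and epidemiologists who want to run
this analysis chain end to end — on their own subject-level tables or on
synthetic cohorts with a known causal structure — and at methodologists who
want a transparent, testable implementation of observed-variable path SEM
with effect decomposition.

## What it computes

**Classification.** Under the harmonised (JIS) criteria a subject is
diagnosed with MetS when at least 3 of 5 components are elevated:
WC ≥ 88 cm (women) / 102 cm (men), TG ≥ 150 mg/dL, HDL-c < 50 (women) /
40 (men) mg/dL, SBP ≥ 130 **or** DBP ≥ 85 mmHg (counted once), FG ≥ 100
mg/dL; drug treatment for a component counts as elevated.

**Path model.** A two-level recursive SEM over observed variables:
age → BMI → each component → MetS status (the component count 0–5 treated as
continuous). Each endogenous variable *y* with parents *x₁…x_k* is fitted on
z-scored data,

  y = β₁x₁ + … + β_k x_k + e,  Var(e) = 1 − R²,

which for a recursive system equals the maximum-likelihood path solution.
Every β gets a Student-t test with df = n − k − 1. The observed correlation
of any pair decomposes into **direct** (the edge β), **indirect** (sum of
coefficient products over directed paths of length ≥ 2) and **spurious**
(observed minus total) effects, via Wright's path-tracing rules. Fit is the
standardized root mean square residual between observed and model-implied
correlations,

  SRMR = √( Σ_{i<j} (r_ij − ρ̂_ij)² / [p(p−1)/2] ),

with the bands perfect (≈0), very good (<0.05), adequate (<0.1), poor.

**Around the model**: Table-style stratified descriptives (means ± SD, 95%
CI, one-decimal percentages), Lilliefors/Levene screens, two-way
(age group × BMI band) Type III ANOVA with classical η² effect sizes
(bands at 0.04 / 0.25 / 0.64) and Tukey–Kramer post-hoc contrasts, and a
synthetic cohort generator calibrated to published per-sex marginals with a
configurable structural skeleton.

## Worked example

```python
import metspath as mp

cohort = mp.generate_cohort(mp.GeneratorConfig(n_women=300, n_men=300, seed=20220313))
results = mp.run_mets_sem(cohort)
for name, res in results.items():
    print(name, res.model.n_, round(res.report.srmr, 4), res.report.category)
```

prints

```
women 300 0.0335 very_good
men 300 0.0529 adequate
total 600 0.0426 very_good
```

i.e. at n=300 per sex the fitted two-level model leaves root-mean-square
correlation residuals of ≈0.03–0.05 — at or near the "very good" band of the
SRMR < 0.05 convention. Individual effects:

```python
d = results["total"].model.decompose_effects("age", "mets")
print(round(d.direct, 3), round(d.indirect, 3))   # 0.0  0.1
```

age has no direct edge to status in this model; its entire total effect
(≈0.1 here) is transmitted through BMI and the components.

The same chain is available from the shell:

```bash
metspath generate --seed 1 --out cohort.csv
metspath run --config my_generator.yaml --out results/ --seed 1
metspath fit-sem --input cohort.csv --subgroup women --out sem.json
```

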