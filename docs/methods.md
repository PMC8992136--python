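# Methods

## The model

The package analyses a two-level recursive structural model over observed
variables in a cohort of adults diagnosed with metabolic syndrome (MetS):

- **Level 1** — age and body composition (BMI) act on each of the six
  component measurements (WC, SBP, DBP, FG, TG, HDL-c); age also acts on
  BMI directly.
- **Level 2** — the components act on MetS status.

The model is *recursive*: the directed graph is acyclic and disturbances are
mutually uncorrelated. Under these assumptions the system is estimable
equation by equation: each endogenous variable is regressed by ordinary
least squares on its direct parents after z-scoring all variables
(denominator n − 1), and this sequential solution coincides with the
full-information maximum-likelihood path solution, so no iterative fitter is
used. Per-edge standardized coefficients β carry classical OLS standard
errors on the standardized scale, Student-t statistics with
df = n − (#parents) − 1 and two-sided p-values. Each endogenous variable
reports R² and the disturbance term 1 − R², the variance share attributed
to unmeasured causes.

**Status operationalization.** MetS status is the harmonised component
count (0–5) treated as a continuous endogenous variable. In an
all-diagnosed sample a binary diagnosis outcome is degenerate, and the
scientific question is about *changes* between 3-, 4- and 5-component
states, which the count captures. Other status columns (e.g. a generated
latent score) can be substituted via `run_mets_sem(..., outcome=...)`;
a categorical-outcome (logit/probit) variant is out of scope.

**Sex.** Sex is handled by subgrouping (women / men / total), not as a
model variable, mirroring the stratified reporting the analysis is built
around.

## Implied correlations, effect decomposition, SRMR

Collect the fitted coefficients in B (B[t,s] = β for edge s→t) and let Ψ
hold the sample correlations of the exogenous block and the disturbance
variances 1 − R² of the endogenous variables. The model-implied covariance
of the standardized system is

    Σ = (I − B)⁻¹ Ψ (I − B)⁻ᵀ

whose off-diagonal entries equal the sum over all valid Wright traces (no
loops, at most one exogenous-correlation link, no forward-then-backward
reversal). The diagonal is fixed at one — the tracing convention for
standardized variables; away from saturation Σ's raw diagonal can drift
slightly from one because the parent blocks of different equations are not
jointly saturated. The test suite checks the matrix identity against an
explicit brute-force trace enumerator on random models of up to six nodes.

For an ordered pair (source, target):

- **direct** = β on the edge source→target (0 if absent);
- **indirect** = Σ over directed paths of length ≥ 2 of coefficient
  products, computed as ((I − B)⁻¹ − I − B)[target, source];
- **total** = direct + indirect;
- **spurious** = observed correlation − total.

Defining the spurious share as the residual (rather than enumerating
common-cause traces separately) is equivalent when the model is correctly
specified and remains well-defined when it is not.

Fit is summarised by the standardized root mean square residual

    SRMR = sqrt( Σ_{i<j} (r_ij − ρ̂_ij)² / [p(p−1)/2] )

over the p(p−1)/2 unique off-diagonal pairs, with qualitative bands
perfect (< 1e−8), very good (< 0.05), adequate (< 0.1), poor otherwise.
Degenerate-input policy: a zero-variance variable, a cyclic specification,
and a parent block with condition number above 1e8 each raise a specific
error rather than being silently repaired.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be exercised and calibrated without patient data:

1. **Ages** are drawn from a per-sex truncated normal on [18, 102] years.
2. The remaining variables are generated in topological order of the
   structural DAG: each is the coefficient-weighted sum of its parents plus
   an independent Gaussian disturbance scaled (from the exactly implied
   covariance) so the population variance is one — the configured
   coefficients are therefore the standardized path weights.
3. Each observed column is affinely rescaled, per sex, to its configured
   marginal mean and SD (the sample is standardized exactly before the
   affine map). Affine maps preserve correlations, so moments and structure
   are controlled simultaneously.
4. Values pushed out of range (e.g. a negative TG) get a fresh disturbance
   — the structural linear part is kept, so truncation does not bias the
   coefficients — and the rescale is recomputed; clipping is used only for
   ages (by construction of the truncated draw, effectively never) and as a
   last-resort safeguard after 20 redraw rounds.
5. BMI is the structural body-composition variable; height is an
   independent per-sex normal and weight is derived as BMI·(height/100)²,
   so the BMI identity holds row-wise exactly. The weight marginal is then
   implied (≈71.6 kg vs the configured table's 71.55 for women) rather than
   imposed.
6. Treatment flags are independent Bernoulli draws with configured rates
   (default 0: the source tables publish none).

Default marginals are the published per-sex values (women n=1914, men
n=1667; e.g. women WC 97.69 ± 11.79 cm). The published age marginals are
internally inconsistent between the text and the table; the table's
assignment (women 64.08 ± 14.23 y) is the default and
`table1_marginals(age_source="text")` selects the other. The men's TG SD is
printed as 13.68 mg/dL, implausibly equal to the SBP SD and far below the
pooled TG SD of 78.85; it is kept as printed because it is the configured
value calibration is checked against, but real male TG dispersion is
certainly larger.

Default structural coefficients are package choices within the reported
qualitative pattern: age→BMI negative (−0.18, matching the reported range),
BMI dominant on WC (0.75), moderate age/BMI effects on the pressures and
glucose, an inverse BMI→HDL path, and component→status weights ordered
WC > FG > SBP > DBP ≈ TG > |HDL|, the reported ordering. A single seeded
`numpy` generator is consumed in a fixed order (women then men; within a
sex: age, structural variables in topological order, height, flags), so a
fixed config is bit-reproducible.

**What the generator does not emulate**: measurement error and digit
preference in field anthropometry, non-Gaussian tails (real TG is right-
skewed; here it is a truncated Gaussian), treatment effects on the treated
values themselves, within-household or within-centre clustering, and any
selection structure of the exclusion cascade. Passing tests therefore show
the *methods* are correct and calibrated under the assumed linear-Gaussian
structure, not that real cohorts satisfy that structure.

## Classification, descriptives, ANOVA

- JIS cutoffs (configurable, defaults: WC ≥ 88/102 cm F/M, TG ≥ 150 mg/dL,
  HDL < 50/40 mg/dL F/M, SBP ≥ 130 or DBP ≥ 85 mmHg counted as one
  component, FG ≥ 100 mg/dL; treatment flag ⇒ elevated). A separate
  anti-diabetic treatment flag is modelled for FG, defaulting to absent.
  Diagnosis ⇔ count ≥ 3. Age groups 18–39 / 40–64 / ≥65 (the ≥65 reading of
  the inconsistent published boundary); BMI bands < 25 (absorbing
  underweight) / 25–29.9 / ≥ 30 kg/m².
- Exclusion rules (age < 18, missing required fields, not diagnosed) are
  applied in that order; the tally under the reversed order is logged for
  transparency since rules overlap.
- Descriptives: percentages rounded half-up to one decimal and means/SDs to
  two, matching the printed precision; 95% CIs use t quantiles (the source
  is silent; at these n the normal quantile is indistinguishable).
  Normality screening uses the Kolmogorov–Smirnov statistic with the
  Lilliefors null (parameters are estimated from the sample); homogeneity
  uses Levene's test with mean centering.
- ANOVA: Type III sums of squares with sum-to-zero contrasts, chosen
  because the study design is unbalanced and this is the convention of the
  commercial package the field defaults to; results can diverge from
  Type I/II conventions on unbalanced data. η² is classical
  (SS_effect/SS_total) by default with partial η² available — the published
  effect sizes are consistent with either. Bands: none ≤ 0.04 < minimum
  ≤ 0.25 < moderate ≤ 0.64 < strong. With a perfectly fitting (zero
  residual) response, F is reported as 0 for absent effects and ∞
  otherwise. Post-hoc: Tukey–Kramer with the studentized-range
  distribution, α = 0.05; singleton levels are excluded with a warning.

## Problem sizes used in the verification suite

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the asserted tolerances: parameter recovery at n = 10,000 over
20 seeds (βs within ±0.03, ≥95% of coefficients), trace-enumeration oracles
on 200 random ≤6-node models at 1e−10, ANOVA type-I error over 1000
replicates of a 48-observation 2×3 null design (accepted band 3.5–6.5% at
α = 0.05), and generator calibration at the study's own subgroup sizes
(means within 3·SD/√n). All seeds are fixed constants.

## Known limitations

- Linear-Gaussian paths only; no latent variables, no measurement model,
  no bootstrap CIs for indirect effects.
- The component count is an ordinal variable treated as continuous; βs on
  the status equation inherit that approximation.
- SRMR is the only fit index; χ², CFI/TLI and RMSEA are not computed.
- The published subject-level estimates themselves (per-edge βs on the real
  cohort) are not reproducible here because the underlying patient data are
  not deposited; the package reproduces the method and the printed
  worked-example arithmetic.
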