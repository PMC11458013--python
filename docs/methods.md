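# Methods

## Cohort model and eligibility

The unit of analysis is a mother with two successive singleton
pregnancies and a measured BMI for her second child at age 4–5 years.
The on-disk format is a wide CSV, one row per mother (column dictionary
in `cohort_io.COLUMN_SPEC`). Only systolic blood pressure and caesarean
delivery may be missing; all other fields are mandatory.

Before analysis an ordered exclusion cascade is applied, each row
attributed to its first failing rule: (1) first antenatal appointment
after 168 days' gestation in either pregnancy (weight measured that late
includes substantial gestational gain); (2) underweight BMI (< 18.5
kg/m²) at either pregnancy start; (3) conception by assisted
reproduction; (4) birth gestation outside 154–301 days; (5) missing or
out-of-window (age outside [4, 5]) second-child measurement. The cascade
is idempotent and its tallies serialise to a flowchart-style JSON.

## Derived quantities

- Maternal BMI categories are half-open: healthy [18.5, 25), overweight
  [25, 30), obese [30, ∞). Half-open resolution of the conventional
  "18.5–24.9 / 25–29.9" wording guarantees every recorded value has
  exactly one category. Values below 18.5 raise: they indicate an
  eligibility bug upstream, not a classifiable input.
- Interpregnancy weight change Δ = BMI₂ − BMI₁: loss (Δ ≤ −1), stable
  (−1 < Δ < 1), moderate gain (1 ≤ Δ < 3), high gain (Δ ≥ 3) kg/m².
  At |Δ| = 1 the gain/loss rules win, because the gain rule's lower
  bound is inclusive.
- Child BMI z-scores come from a pluggable growth reference. A normal
  reference uses (bmi − mean)/sd; an LMS reference uses the Cole
  transformation ((bmi/M)^L − 1)/(L·S) with the log-limit as L → 0.
  Lookup linearly interpolates between tabulated ages within sex and
  clamps at the table ends; whether real analyses should interpolate or
  take the nearest tabulated age is a convention the user can control by
  tabulating finely. The packaged default is a flat synthetic normal
  reference (mean 16, SD 1.3 kg/m², ages 4–5) so nothing external need
  be downloaded; real references load from a CSV of (sex, age_years, L,
  M, S).
- Adiposity flags: overweight/obesity at z ≥ +1.04 (85th centile),
  obesity at z ≥ +1.65 (95th centile); obesity therefore implies
  overweight/obesity.

## The estimation engine

`fit_models` fits, in the configured causal order (default smoking₂ →
BMI₂ category → SBP₂), one model per pregnancy-2 covariate on the
baseline confounders (ethnicity, education, employment, maternal age),
the pregnancy-1 exposures (BMI₁ category, smoking₁, SBP₁) and all
covariates earlier in the order; then a logistic outcome model per
outcome definition on all of the above. Families: logistic (binary),
multinomial-logistic (3-level BMI category), linear-Gaussian (SBP).
Birth-2 variables (birthweight, gestation, caesarean) are *never*
outcome-model predictors: they are descendants of the intervened
exposures, and conditioning on them would block part of the total
effect. The default ordering encodes behaviour → anthropometry →
physiology; it is a configuration knob, and order-insensitivity can be
checked by permuting it.

`simulate_scenario` replicates each subject `n_copies` times (default
10), holds baseline and pregnancy-1 values fixed, draws pregnancy-2
covariates sequentially from the fitted models, overwrites intervened
covariates (BMI₂ category set to the scenario's level; smoking₂ set to
0 under cessation), and averages the *fitted outcome probability* over
all copies — averaging probabilities rather than sampled outcomes
removes one layer of Monte-Carlo noise, so the simulation variance
shrinks like 1/(n·n_copies). The natural course is simulated, not read
off the data, which enables the natural-course-consistency diagnostic
(scenario-0 estimate ≈ raw prevalence).

Every scenario re-draws from an identically seeded stream with a
scenario-independent number of draws (common random numbers): a no-op
intervention reproduces the natural course bit for bit, and scenario
contrasts are not inflated by independent simulation noise.

Maternal age at pregnancy 2 is deterministic given the interpregnancy
interval and is never simulated. Rows with missing SBP are dropped
complete-case with a logged count before fitting and simulation.

Stratified analyses (by pregnancy-1 BMI category) re-run the entire
fit-and-simulate procedure independently within each stratum, so every
stratum gets stratum-specific models; strata below a configurable
minimum size are skipped with a warning.

### Saturated mode

For verification on fully discrete data the engine supports a saturated
mode in which each model's additive terms are replaced by the full
cross-classification of its predictors and the fit is the exact MLE —
the empirical cell proportions (computed directly; a saturated logistic
fit converges to the same numbers). Cells unobserved at fit time fall
back to the marginal distribution. This mode exists to make the engine
comparable against closed-form standardization without approximation
error. It is a verification device, not the recommended analysis
estimator: with realistic sample sizes its empty-cell fallback biases
exactly the rare intervened cells that parametric smoothing handles.

### Numerical choices

Non-saturated logistic fits use scikit-learn with a very weak L2 ridge
(C = 10⁴, i.e. effectively unpenalized at these sample sizes) purely to
stabilise near-separated sparse categories (e.g. rare ethnicity levels
inside the obese stratum); solvers are lbfgs (binary, tol 1e-5) and
newton-cg (multinomial, tol 1e-5), capped iterations. Benchmarked
against tight-tolerance fits, the predicted-probability drift from these
caps is ≤ 0.15 pp at the cell level and ≪ 0.01 pp on standardized
prevalences — far below the sampling noise any analysis of ~5600
mothers carries. Continuous predictors are standardized with training
moments; categoricals are one-hot with first level dropped.

## Effect measures and the bootstrap

Point estimates come from the original sample. B resamples of mothers
with replacement (the mother is the resampling unit; eligibility is
applied once, before resampling) each re-run the full fit-and-simulate
procedure; 95% CIs are the 2.5th/97.5th percentiles of the replicate
values. Ratios and differences are formed *within* each replicate
against that replicate's own natural course, preserving their
dependence; combining marginal CIs would not. Replicate engine seeds
derive from the master seed by a documented counter
(`master·1 000 003 + b + 1 mod 2³¹`), so replicates are reproducible
individually. A replicate whose fit fails is dropped and counted; more
than 10% failures aborts. If the natural-course prevalence is zero the
risk ratio is undefined and reported as NaN with a logged warning.
The percentile bootstrap (rather than normal-approximation or BCa) is
the distribution-free default of standard g-formula software.

## The synthetic cohort generator

The generator is an explicit structural model calibrated to published
descriptive marginals for a cohort of 5612 two-pregnancy mothers:

- Stratum (pregnancy-1 BMI category) probabilities 3409/1466/737 ÷ 5612.
- Within-stratum BMI₁ truncated normal at the category bounds with means
  (SD) 22.0 (1.7), 27.0 (1.4), 34.3 (4.0); truncation guarantees
  category consistency.
- BMI₂ = BMI₁ + Δ, with Δ drawn from a four-component per-stratum
  mixture matching the published weight-change category frequencies
  (stable/loss/moderate/high gain); within categories the shapes are
  uniform on (−1, 1) for stable, −1 − Exp(2.75) for loss, uniform on
  [1, 3) for moderate gain, and 3 + Exp(1.5) capped at +10 for high
  gain — the component shapes are the generator's own choice, the
  frequencies are the calibration targets. The heavy-tailed loss
  component matters: it gives every stratum positive probability of
  reaching every pregnancy-2 category (positivity), with implied
  category-maintenance rates (~79%/58%/91%) and an obese-to-healthy
  transition share (~1.5%) matching the published transition summary.
  BMI₂ is floored at 18.51 (eligibility excludes underweight).
- Smoking: stratum-specific pregnancy-1 prevalences (14.8/14.7/17.0%),
  a 2×2 transition with a fixed uptake rate of 2% among pregnancy-1
  non-smokers, and persistence solved per stratum so the pregnancy-2
  marginals (13.2/12.8/16.0%) are matched. Uptake is a documented free
  parameter: only the two marginals are published, not the joint.
- SBP, age, ethnicity, education, employment, interval, birthweights,
  gestations and caesarean rates follow the published per-stratum
  means/SDs or frequencies; SBP₂ correlates 0.5 with SBP₁. Ethnicity,
  education and employment are generated but carry zero structural
  effect on the outcome by default — they are confounders only if the
  user wires them in.
- Small fractions of SBP and caesarean values are set missing (1.0%,
  1.8%, 0.2%, 1.4%) to exercise the complete-case path.

**Child outcome.** A latent z-score z = α_s + 0.12·[BMI₂ overweight] +
0.25·[BMI₂ obese] + 0.25·smoking₂ + ε, ε ~ N(0,1), thresholded at
+1.04/+1.65, generates both outcome definitions from one latent
variable, so obesity is nested in overweight/obesity by construction.
The effect sizes are structural constants chosen to give scenario
contrasts of the magnitude reported for maternal adiposity and smoking
exposures (relative risks ~0.7–0.9 for moving the obese stratum to a
healthy BMI, ~0.93 for universal cessation).

**Calibration.** The stratum intercepts α_s are solved by Brent
root-finding so that the implied factual overweight/obesity prevalence
per stratum — E[1 − Φ(1.04 − α − b·x)] over a fixed Monte-Carlo draw of
pregnancy-2 covariates — matches the targets (17.19%, 25.85%, 38.13%).
The implied prevalence is strictly increasing in α, so the root is
unique; the obesity prevalences then follow from the same latent
variable and land within ~0.5 pp of their observed values (5.84%,
10.23%, 17.64%) without being targeted.

Because the structural model is explicit, true counterfactual
prevalences under any scenario are computable by applying the overrides
at the structural level and integrating the latent noise analytically
(`true_counterfactual_prevalence`); these serve as ground truth for the
unbiasedness and coverage experiments.

**What the generator does not emulate.** Only the published marginals
are matched; the real joint distribution (e.g. the dependence of weight
change on age or deprivation, interval effects, measurement error in
self-reported smoking) is not modelled, and the interpregnancy interval
has no structural role. Passing tests therefore demonstrate that the
estimator recovers the truth *of this structural family* — they cannot
certify behaviour under misspecification patterns the generator does
not contain.

## Verification strategy

1. **Exact oracle.** On fully discrete joints the g-formula has a closed
   form; `oracle.exact_standardization` evaluates it and is itself
   checked against an independently written brute-force enumeration on
   100 random instances to 1e-12.
2. **Engine vs oracle.** Cohorts sampled from discrete joints, engine in
   saturated mode: |engine − oracle| < 0.5 pp at n·n_copies ≥ 10⁵. The
   cohort-sampling stream is deliberately decoupled from the engine's
   simulation stream; with a shared seed the inverse-CDF draws are the
   same uniforms and induce spurious correlation.
3. **Parameter recovery and coverage.** 200 synthetic datasets
   (n = 2000), percentile bootstrap with B = 100 (scaled down from the
   default 250), main-effects parametric models: scenario-prevalence
   estimates unbiased within 1 pp of the structural truth, CI coverage
   within [90%, 98%]. The parametric models matter here: assigning the
   obese stratum a healthy pregnancy-2 BMI asks about cells observed in
   only ~2% of that stratum, and a saturated cell estimator is visibly
   biased at n = 2000 by its empty-cell fallback — smoothing across
   cells is precisely the parametric g-formula's job.
4. **Full pipeline.** n = 5612, 8 scenarios, 2 outcomes, B = 250,
   whole-sample plus three strata: completes in well under 15 minutes on
   one CPU (~4 minutes in development) and is byte-for-byte seed-
   reproducible.

## Known limitations

- Two time periods only; no time-varying g-formula beyond the
  two-pregnancy structure, no IPW or g-estimation alternatives, and no
  dynamic (covariate-responsive) intervention rules.
- Pregnancy-2 BMI enters as a 3-level category, because the static
  interventions are defined on categories; a continuous-BMI intervention
  would need a within-category distribution the data do not identify.
- The packaged growth reference is synthetic; real analyses must supply
  an LMS table.
- Percentile intervals can be erratic when a stratum is small and an
  intervention is rare in it (wide, occasionally order-inverted bounds);
  the table reports them as computed.
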