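# pregformula

Parametric g-formula (g-computation) analysis of how hypothetical
changes in a mother's BMI and smoking status **between her first two
pregnancies** would alter the prevalence of overweight/obesity and
obesity in her second child at age 4–5 years.

The package is written for perinatal and life-course epidemiologists who
work with routinely collected two-pregnancy maternity records linked to
measured child BMI (e.g. school-entry measurement programmes). Such
cohorts are rarely publicly deposited, so the package ships a calibrated
synthetic cohort generator with known ground truth; every statistical
claim in the test suite is checked against that generator or against an
exact discrete oracle.

## The method

For each mother we observe baseline confounders `V` (ethnicity,
education, employment, age), first-pregnancy exposures `X₁` (BMI
category, smoking, SBP) and second-pregnancy exposures `X₂`, and the
child-2 outcome `Y` (BMI z-score ≥ +1.04 → overweight/obesity; ≥ +1.65 →
obesity). The g-formula estimate of prevalence under a static
intervention `x₂*` is

    P(Y^{x₂*} = 1) = Σ_v Σ_{x₁} P(v, x₁) · E[ Y | v, x₁, do(X₂ = x₂*) ]

estimated by fitting causally ordered parametric models — logistic for
smoking₂, multinomial-logistic for BMI₂ category, linear-Gaussian for
SBP₂, logistic for the outcome — then replicating every subject
`n_copies` times, drawing `X₂` sequentially from the fitted models,
overwriting any intervened component, and averaging the fitted outcome
probability. Scenario 0 (the *natural course*, no overwriting) is the
comparator for the population risk ratio `p_s / p_0` and population mean
difference `(p_s − p_0) × 100` percentage points. 95% CIs come from a
nonparametric percentile bootstrap over mothers (default B = 250).

The eight built-in scenarios: natural course; assignment of everyone's
pregnancy-2 BMI to the healthy / overweight / obese category; universal
smoking cessation; and each BMI assignment combined with cessation.

## Worked example

```python
import pregformula as pf

params = pf.default_params()                   # calibrated structural model
cohort = pf.generate_cohort(params, 5612, seed=1)
analysed, flow = pf.apply_eligibility(cohort)  # nothing excluded: eligible by construction

config = pf.ModelConfig(seed=3)
effects = pf.bootstrap_cis(analysed, config, B=250, seed=3)
r0 = effects.row("whole", 0, "overweight_obesity")
r1 = effects.row("whole", 1, "overweight_obesity")
print(f"natural course: {r0.prevalence_pct:.2f}% ({r0.prevalence_lo:.2f}, {r0.prevalence_hi:.2f})")
print(f"scenario 1:     {r1.prevalence_pct:.2f}% ({r1.prevalence_lo:.2f}, {r1.prevalence_hi:.2f}), "
      f"RR {r1.risk_ratio:.2f} ({r1.rr_lo:.2f}, {r1.rr_hi:.2f}), "
      f"MD {r1.mean_difference:.2f} pp")
```

prints (B = 250):

```
natural course: 21.95% (20.97, 23.02)
scenario 1:     19.87% (18.11, 21.78), RR 0.91 (0.83, 0.98), MD -2.08 pp
```

i.e. in this synthetic cohort, if every mother began her second
pregnancy in the healthy BMI range, child-2 overweight/obesity at age
4–5 would fall from 22.0% to about 19.9% — a two-percentage-point
absolute reduction, with a bootstrap risk-ratio interval excluding no
change.

The same analysis from the shell, including the per-stratum tables and a
run manifest:

```bash
pregformula run --synthetic-n 5612 --seed 1 --bootstrap 250 --stratified --outdir results/run1
pregformula run --cohort my_cohort.csv --seed 1 --outdir results/run2   # your own data
```

Other subcommands: `pregformula generate` (write a synthetic cohort
CSV), `pregformula validate` (schema and invariant checks),
`pregformula oracle-check` (Monte-Carlo engine vs exact standardization
on a random discrete instance).

## Layout

- `cohort_io` — wide one-row-per-mother CSV schema, validation, results writer
- `derivations` — BMI categories, interpregnancy weight change, BMI z-scores
  (normal or LMS references), child adiposity flags, eligibility cascade
- `engine` — causally ordered model fitting and Monte-Carlo standardization
- `effects` — risk ratios, mean differences, percentile bootstrap
- `oracle` — exact standardization on discrete joints (verification)
- `synthetic` — calibrated structural cohort generator with true counterfactuals
- `cli` — the `pregformula` command

See `docs/methods.md` for the modelling assumptions, calibration
procedure, numerical choices and known limitations.
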