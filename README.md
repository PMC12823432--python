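# organclock

Organ-specific proteomic aging clocks: from tissue-expression-based
organ-enriched protein mapping, through gradient-boosted age clocks
with Boruta/SHAP feature selection and recursive-feature-elimination
sparsification, to aging phenotypes (age gaps, extreme ageotypes,
multi-organ burden) and the survival/logistic association statistics
built on them.

## The problem

Plasma proteomics can estimate a person's biological age: a regressor
trained to predict chronological age from protein levels yields a
*proteomic age*, and its residual after regressing on chronological age
— the **age gap** — indexes accelerated or delayed aging relative to
same-aged peers. Restricting the predictor set to proteins whose
encoding genes are expressed predominantly in one organ yields
*organ-specific* clocks, so aging can be resolved into brain, heart,
kidney, … components and each organ's gap related to disease risk.

This package implements that full pipeline for researchers in
biostatistics and molecular epidemiology. Because population-biobank
proteomics is access-restricted, the package includes a synthetic
cohort generator with planted ground truth (which proteins are
organ-enriched, which carry age signal, each subject's latent per-organ
aging offset, the true outcome hazards), so every stage is testable
end-to-end and recovery of the planted truth is the test.

## Method summary

- **Organ mapping** — a gene is organ-enriched when its organ-collapsed
  expression (max over tissue subtypes) is ≥4-fold that of every other
  organ, confirmed by re-applying the same rule to a second expression
  resource.
- **Preprocessing** — drop proteins missing in >20% of subjects, then
  subjects missing >50% of retained proteins; rescale each protein to
  [0, 1] and center on the median; never impute (the trees handle
  missing values natively).
- **Clocks** — LightGBM regression of decimal age; 7:3 train/test
  split; random-search hyperparameter tuning maximizing mean 5-fold CV
  R²; Boruta selection (remove features whose mean |SHAP| falls below
  the best permuted shadow feature, iterate to stability); retune,
  refit, evaluate on the held-out set; out-of-fold prediction gives
  every subject a proteomic age from a model that never saw them.
- **Refinement** — SHAP-guided recursive feature elimination down to
  one protein; the minimal panel keeps ≥85% of the full-panel CV r².
- **Phenotypes** — age gap (OLS residual), ageotypes at ±1.5 s.d.,
  extreme-organ burden groups {0, 1–2, 3–4, 5+}, five combined-score
  bins at ±0.5/±1.5 s.d.
- **Associations** — Cox (Efron ties) and logistic models per 1 s.d. of
  exposure with covariates, Benjamini–Hochberg FDR within declared
  families, relative contributions, MCI/distress transition rules,
  multimorbidity, 1:5 age/sex matching, paired-bootstrap AUC
  comparison, Kaplan–Meier cumulative incidence.

See `docs/methods.md` for assumptions, parameter defaults, and what the
generator does and does not emulate.

## Worked example

Train an organismal clock on a simulated cohort (800 subjects, 60
proteins of which 6 carry age signal, 5% missingness) and test whether
the resulting age gap predicts a simulated mortality outcome whose true
hazard depends on the latent aging offset:

```python
import numpy as np, scipy.stats as st
from organclock import (SimulationConfig, OutcomeSpec, SearchSpace,
                        simulate_cohort, train_clock, compute_age_gap, fit_cox)
from organclock.preprocess import preprocess_cohort

cfg = SimulationConfig(
    n_subjects=800, organs=("organismal",), n_proteins_per_organ=60,
    frac_age_informative=0.1, seed=7,
    outcome_specs=(OutcomeSpec("mortality", log_hr=np.log(1.5),
                               baseline_hazard=0.028),),
)
cohort, _, _, truth = simulate_cohort(cfg)
clean, qc, _ = preprocess_cohort(cohort)
model = train_clock(clean.values, clean.age, "organismal",
                    list(clean.values.columns), SearchSpace.desk(10), seed=7)
print(f"selected {len(model.selected_proteins)} of {clean.values.shape[1]} proteins")
print(f"held-out r = {model.evaluation['test_r']:.3f}, r2 = {model.evaluation['test_r2']:.3f}")
r = st.pearsonr(model.oof_age, clean.age)[0]
print(f"out-of-fold r(proteomic age, age) = {r:.3f}")

gaps, _ = compute_age_gap(model.oof_age, clean.age)
df = cohort.outcomes["mortality"].assign(age_gap=gaps)
res = fit_cox(df, "mortality", "age_gap")
print(f"HR per 1 s.d. age gap = {res.effect:.2f} "
      f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), p = {res.p:.2e}")
```

Output:

```
selected 6 of 60 proteins
held-out r = 0.938, r2 = 0.879
out-of-fold r(proteomic age, age) = 0.934
HR per 1 s.d. age gap = 1.36 (95% CI 1.20-1.54), p = 8.87e-07
```

Boruta recovered exactly the six planted age-informative proteins; the
clock correlates 0.93 with age out-of-fold; and the age gap carries the
planted mortality signal (the estimate of 1.36 sits below the
generating hazard ratio of 1.50 per 1 s.d. of the *latent* offset
because the gap is a noisy estimate of that offset — classical
attenuation, not bias in the fit).

The same stages are available from the shell:

```bash
organclock simulate --out sim/
organclock pipeline --out run/        # full simulate→…→associate pass
organclock train --cohort sim/cohort.tsv --organ organismal --out model/
```

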