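# Methods

## Scope

`organclock` implements an organ-resolved proteomic aging-clock
pipeline: mapping organ-enriched plasma proteins from tissue-level
expression, training gradient-boosted age clocks with shadow-feature
selection, sparsifying them by recursive feature elimination, deriving
aging phenotypes (age gaps, extreme ageotypes, multi-organ burden,
combined risk bins), and running the downstream survival/logistic
association harness. Real population-biobank proteomics is
access-restricted, so the package ships a synthetic cohort generator
whose planted ground truth makes every stage testable; all empirical
claims in this repository are recovery results on that generator, not
statements about any human cohort.

## Organ-enriched protein mapping

Tissue columns of a gene-by-tissue expression matrix (TPM-like,
nonnegative) are collapsed to organs by the per-organ maximum over
tissue subtypes. A gene is *organ-enriched* when its collapsed
expression in one organ is at least fourfold (configurable) that of
every other organ; the boundary case qualifies ("at least"), a
runner-up of exactly zero with positive top expression qualifies with
unbounded fold, and the rule can hold for at most one organ, so
assignments are unique by construction. Calls are confirmed by
re-applying the identical organ-collapsed rule to a second, independent
expression resource; by default a protein absent from the confirmation
resource is dropped (a lenient mode keeps it unconfirmed). Ratios are
taken on raw expression units — the test is invariant to common
rescaling, so no log transform is applied. Tissues can be mapped to an
`"other"` pseudo-organ that competes in the ratio test but can never
receive an assignment.

Per-organ protein profiles are summarized by the first principal
component of the standardized organ-protein submatrix (missing entries
mean-imputed for this summary only), with the loading vector oriented
so its largest-magnitude entry is positive; the organ×organ correlation
matrix of subject scores quantifies how independent the organ axes are.

## Preprocessing

Proteomic values are log2-scale relative quantities with missingness.
QC drops proteins missing in more than 20% of subjects, then subjects
missing more than 50% of the *retained* proteins; both thresholds are
strict inequalities (a protein missing in exactly 20% is kept).
Retained values are rescaled per protein to [0, 1] and centered on the
median of the scaled values; missing entries are left missing, because
the tree learner routes missing values to the loss-minimizing split
side natively and imputation would discard that information. The
(min, max, median) triple per protein is stored so external cohorts can
be projected under frozen training parameters; the default instead
re-estimates scaling within each cohort, matching the situation where
cohorts are profiled and normalized separately. Within a cohort,
scaling is estimated on the full analysis sample before the train/test
split: per-protein min/max/median are weak, age-agnostic summaries, so
the leakage risk is negligible, and the frozen-parameter path
(`preprocess_cohort(..., scaling_params=...)`) provides the strict
train-only alternative when that guarantee matters. Decimal age is the
calendar-day count from an assigned birth date (first day of the birth
month) to the visit, divided by 365.25.

## Clock training

Each clock is a LightGBM regressor of chronological age on a candidate
protein set — all proteins for the organismal clock, one organ's
confirmed enriched proteins for the organ clocks. The recipe:

1. **Split.** Subjects are partitioned 7:3 into training and held-out
   test sets (seed-deterministic simple random split; no
   stratification).
2. **Tune.** Seeded random search (default 200 configurations at full
   scale; the desk default used throughout the tests is 30) over
   learning rate (log-uniform 0.02–0.2), leaf count (7–63), minimum
   leaf size (10–80), and feature/row subsampling (0.5–1.0), with up to
   400 trees and early stopping (25 rounds) on each validation fold.
   The objective is mean out-of-fold R² over 5-fold cross-validation;
   the winning configuration freezes its tree count at the mean
   early-stopped iteration.
3. **Boruta selection.** Each trial builds one shadow feature per
   surviving protein by independently permuting its column, fits the
   regressor on real + shadow features, and computes per-feature
   importance as the mean |TreeSHAP| attribution on the training data
   (LightGBM's native `pred_contrib`). Every real feature whose
   importance falls below the *maximum* shadow importance — the 100%
   threshold — is removed. Trials repeat (up to 200) until a trial
   removes nothing. The survivor set therefore shrinks weakly
   monotonically, and shadow features can never be returned.
4. **Retune and refit.** Hyperparameters are re-searched on the
   selected panel and the final model is fit on the training set;
   Pearson r and R² are reported on the untouched test set.
5. **Out-of-fold ages.** Proteomic age for *every* subject comes from
   a fresh k-fold fit on the full sample: each subject is predicted by
   the one model whose training fold excluded them. Projection onto an
   external cohort averages the fold ensemble.

All LightGBM fits run single-threaded with `deterministic=True` and
`force_row_wise=True`, so the entire pipeline is byte-reproducible
under a master seed.

## Recursive feature elimination

Starting from the Boruta-selected panel, models are refit with k-fold
cross-validation at every panel size; mean out-of-fold r² and mean
|TreeSHAP| importance (averaged over folds) are recorded, the
least-important protein is eliminated (importance ties break to the
lexicographically smallest id), and the loop continues to a single
protein. The minimal panel is the smallest size retaining a stated
fraction (default 85%) of the full-panel r² — an explicit, auditable
stand-in for picking the knee of the r² curve by eye; a kneedle-style
elbow detector is available as an alternative. Hyperparameters are
held fixed along the path: re-tuning at every size would make the cost
quadratic in panel size and changes only the ranking noise, not the
ranking mechanism. This is a deliberate simplification and the main
deviation risk of the module.

## Aging phenotypes

The *age gap* is the residual of proteomic age OLS-regressed on
chronological age (slope and intercept stored for frozen application to
projected cohorts), so gaps are mean-zero and age-uncorrelated on the
fitting sample by construction. *Extreme ageotypes* label an organ aged
(gap > +1.5 cohort s.d.) or youthful (gap < −1.5 s.d.), with the s.d.
estimated on the analysis sample and frozen for external use. Burden
groups count extreme organs per subject into {0, 1–2, 3–4, 5+}
(the organismal clock is excluded from the count). Two standardized
risk scores are combined as the re-standardized mean of the z-scores
and binned at ±0.5 and ±1.5 s.d. into five strata; intervals are closed
on the left, so a score exactly at a cut point falls in the upper bin.
A sum-without-restandardization mode is available
(`restandardize=False`).

## Association harness

Cox proportional-hazards models (lifelines, Efron tie convention)
report hazard ratios per 1 s.d. of the exposure — the exposure is
divided by its analysis-sample s.d. before fitting, which makes the
reported effect invariant to linear rescaling. Logistic models
(statsmodels MLE) report odds ratios per 1 s.d. Non-convergence, fewer
than 10 events, or suspected separation produce flagged results that
are excluded from multiplicity correction. Benjamini–Hochberg q-values
are computed by the step-up rule within user-declared families (the
pipeline declares one family per outcome). Relative contributions scale
|z| of q-significant terms to sum to 1. A scaled Schoenfeld-residual
test is available as a proportional-hazards diagnostic.

Transition labels: MCI is a cognitive score ≥1.5 s.d. below the
education-stratum baseline mean of cognitively normal (externally
flagged, e.g. disease-free) subjects, boundary inclusive; psychological
distress is a PHQ-4-like score ≥ 6, inclusive. Multimorbidity is ≥2
incident diseases within a category (and across categories combined).
Case–control matching draws up to 5 controls per case within ±2 years
of age and the same sex, without replacement across the whole matched
set. AUC comparison fits each logistic model once and resamples
subjects' fitted scores in a paired bootstrap (default 2,000 draws;
draws missing a class are redrawn), with a two-sided percentile p on
the AUC difference; refitting per draw was rejected as ~1000× the cost
for a near-identical null distribution at these sample sizes.
Cumulative incidence is 1 − Kaplan–Meier per group. Lifestyle risk
categories map unhealthy-factor counts to favorable (0–2),
intermediate (3–5), unfavorable (6–9).

## Synthetic cohort generator

The generator emulates the data structure the method assumes, with the
simplest distributional forms consistent with it:

- **Ages** uniform on 37–70 years; sex Bernoulli(0.5); two continuous
  covariates (BMI-like, activity-like).
- **Ten organ systems** by default (brain, heart, lung, immune, artery,
  intestine, liver, kidney, muscle, pancreas), each with ≥2 tissue
  subtypes. Planted enriched genes sit 8-fold (configurable) above the
  background level in their organ in *both* the discovery-like and
  confirmation-like matrices, under independent multiplicative
  lognormal noise (σ = 0.2 by default).
- **Proteome**: an age-informative protein of organ g follows
  `intercept + slope·(age + offset_g) + quad·max(0, age + offset_g −
  55)² + N(0, noise_sd)`; slope magnitudes are uniform on
  0.03–0.08 log2-units/year with random sign, a quarter of informative
  proteins get an accelerating quadratic ramp after age 55 with
  curvature proportional to their slope, and all other proteins are
  age-independent noise. Defaults (noise_sd = 0.3, 10% of proteins
  informative) put single-protein age correlations around 0.3–0.6,
  i.e. individually informative but individually insufficient, which is
  the regime the feature-selection machinery is built for.
- **Latent aging offsets**: Normal(0, 3 years) per subject×organ. The
  3-year s.d. is a placeholder calibrated for test power — the
  within-cohort spread of true organ age gaps in years is not an
  empirically anchored quantity here.
- **Missingness** is completely at random (default 5%).
- **Outcomes**: exponential proportional-hazards event times with
  linear predictor `Σ_g β_g·offset_g/sd(offset_g)` plus optional
  covariate terms, administratively censored at a horizon (default 13
  years); binary transitions use the analogous logistic model.
- Each stage draws from its own random stream split from the master
  seed, so stages regenerate independently and identical configurations
  reproduce byte-identical outputs.

What the generator does **not** emulate: batch/plate effects,
informative or limit-of-detection missingness, longitudinal repeat
sampling, genotype structure, non-proportional hazards, and realistic
correlation between organ offsets (they are independent by default).
Passing recovery tests therefore demonstrates that the machinery is
correct and well-calibrated under its own assumptions, not that the
clocks would attain any particular accuracy on real plasma proteomics.

## Problem sizes and numerical choices

Simulation-based checks run at desk scale, chosen to keep the full
suite inside a typical CI budget while leaving wide statistical
margins: clock recovery at n = 2,000 subjects × 200 proteins (20
informative) with 30 tuning trials; Boruta recovery at n = 1,000 with
5 planted among 50 over five seeds; hazard recovery at n = 5,000 with
~30% events; calibration checks at 100–500 replicates; the end-to-end
byte-determinism run at n = 320 with three organs. Paper-scale
settings (200 tuning trials) remain one constructor argument away
(`SearchSpace(n_trials=200)`).

Degenerate inputs are handled explicitly: constant proteins are dropped
at scaling (undefined range); constant chronological age is an error
for gap regression and clock fitting; zero-variance gaps are an error
for ageotyping; organs with fewer than two measured proteins are
skipped with a warning; an empty Boruta survivor set is returned with a
warning and the pipeline falls back to the full candidate set.
Floating-point output uses a fixed `%.10g` format everywhere, which is
what makes end-to-end byte-identity a meaningful contract.
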