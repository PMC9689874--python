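# Methods

This note documents the statistical procedures, the synthetic-data
generator, the numerical choices and the known limitations of `mrsbp`.

## Phenotype harmonization

Blood pressure comes as up to three automated readings per participant.
Readings are censored **per trait and per reading**: an SBP value strictly
above 250 mmHg is dropped while its paired DBP reading is kept, and a DBP
value strictly below 40 mmHg likewise; boundary values (exactly 250 or 40)
are retained. A `censor_pairwise` switch drops both members of an offending
pair instead, for users whose source data censored whole measurements; it
defaults to off because trait-wise censoring is the least destructive
reading of the protocol. The harmonized value is the mean of the surviving
readings, and the medication adjustment — +15 mmHg SBP, +10 mmHg DBP for
participants on antihypertensive medication — is applied **after**
averaging. A participant with no surviving readings gets a missing outcome.

Covariate codings: type-2 diabetes is hypoglycemic/insulin medication use
or fasting glucose ≥ 126 mg/dL (boundary inclusive; undecidable when the
observed branch is negative and the other missing). Alcohol use is
nondrinker / occasional / heavy with sex-specific bounds (≤ 1 drink/day for
females, ≤ 2 for males counts as occasional). Parental education is
dichotomized to "all parents under 12 years of schooling", with the
legacy categorical form mapping `<8` to the under-12 group and `8+` to
missing, since that category cannot resolve the 12-year cut. Educational
attainment is carried both as the 3-level factor (used for covariate
adjustment) and as two dummies — high-school degree and at-least-some
college — which replace the factor in interaction models.

## Methylation adjustment

Each CpG's beta values are modelled by REML as intercept + cell fractions
(fixed effects) + chip (random intercept) + slide (random intercept). Two
choices deserve emphasis:

* **Conditional residuals.** "Adjusted methylation" here means the
  observed value minus the fixed-effect fit *and* minus the predicted
  (BLUP) chip and slide intercepts. The purpose of the adjustment is to
  remove batch variance from the values that enter the risk scores, so
  predicted random effects are subtracted, not merely estimated. Because
  BLUPs are shrunken, tiny batches retain a correspondingly larger share of
  their batch effect; the test suite's equivalence check against hard
  batch-mean removal therefore uses large batches. Residuals are re-centered
  to mean zero per CpG; users comparing absolute methylation levels should
  note the intercept is gone.
* **Nested random effects.** Slides are modelled as nested within chips
  (chip as the grouping factor, slide as a variance component inside it).
  With globally unique slide identifiers — validated on input, a slide id
  appearing under two chips is rejected — the nested and crossed
  formulations coincide, and the nested form is substantially faster.

One cell-fraction column (by default the last) is dropped before fitting
because the fractions sum to one and would otherwise be collinear with the
intercept; the dropped column is recorded in the output. A fallback ladder
handles degenerate inputs: drop the slide component, then the chip
component, then plain OLS on the cell fractions; a constant CpG short-
circuits to zero residuals and zero variance components. Every CpG's path
through the ladder is reported alongside its chip/slide/residual SDs.

## Risk scores

The MRS is `Σ_j w_j · adjusted_ij` over the weighted CpGs; the weight table
is a required input (the published EWAS weights are not redistributable, so
a clearly labelled synthetic stand-in with uniformly negative weights on
the mmHg-per-beta-unit scale ships with the package). With negative
weights, a larger score means lower overall methylation and higher blood
pressure; the package asserts this orientation as a property test rather
than flipping signs internally. Outliers are flagged on the **raw** scores
(|score − mean| > 5 SD, moments over all raw scores), then the
standardization moments are recomputed on the survivors — exclusion
precedes standardization. The MRS is standardized over the whole analytic
sample by default (a flag enables within-ancestry standardization); the
GRS, built from ancestry-specific weights, is always standardized within
ancestry. GRS dosages are oriented to the weight table's effect allele,
flipping mismatches as 2 − dosage; flipping an allele and negating its
weight is a no-op up to an additive constant, which the tests verify.
Outlier exclusion is applied after merging scores with the analysis sample.

Genotype PCs are the top 10 components of the column-standardized dosage
matrix (monomorphic SNPs dropped, sign fixed so each component's largest
loading is positive). LD pruning before PCA is standard practice on real
genotypes but is not implemented: the simulated SNPs are independent by
construction, so there is nothing to prune. Stratified analyses recompute
PCs within the stratum.

## Association models

All fits are OLS (or WLS with HC1 sandwich errors when a sampling-weight
column is specified — weights-only, since bare per-person weights carry no
strata or cluster information). Model 1 adjusts for age, sex and 10
genotype PCs; Model 2 adds smoking, alcohol, BMI, exercise, diabetes,
education and parental education. Reference levels: male sex, never-smoker,
nondrinker, less-than-high-school. Listwise deletion is applied per model
spec, which is why the fully adjusted n is smaller. p-values are two-sided
and t-based. Per-CpG coefficients are rescaled by ×0.01 to mmHg per 1%
methylation for reporting; the Bonferroni threshold for 13 CpG tests is
α/13 (0.0038 at α = 0.05).

Interaction models add one multiplicative score-by-modifier term.
Continuous modifiers (age, GRS) are standardized **using the analysis
subsample's own moments**, which are emitted with every fit — percentile
contrasts are only reproducible given the exact moments used, so they are
first-class output rather than an internal detail. Effect-at-level
contrasts are β_MRS + β_int·z with the delta-method SE from the coefficient
covariance; at z = 0 the contrast returns the main-effect coefficient
itself, with no recomputation. Cochran's Q compares stratum estimates with
inverse-variance weights against χ²(K−1). The variance-partition menu
(covariates / +MRS / +GRS / +MRS+GRS) is always refitted on the single
common listwise-deleted sample so the four adjusted R² values are
comparable; they are reported as percents to one decimal with full
precision retained in machine output.

## The synthetic cohort generator

The generator emulates the cohort structure the analysis assumes: n = 3070
older adults, 58.5% female, age 70.5 ± 9.5 years, education split
15.5/33.0/51.5%, 57.7% on antihypertensive medication, BMI 29.9 ± 6.2,
ancestry labels EA/AA/other at 65.8/14.2/20.0%, and per-field covariate
missingness chosen to reproduce the observed shrinkage from the minimally
to the fully adjusted analysis sample (~12% listwise loss, dominated by
parental education and BMI).

Methylation: beta_ij = clip(baseline_j + loadings_j·(fractions_i − prior
mean) + chip + slide + s_ij, 0, 1), with cell fractions from a 6-component
Dirichlet prior mimicking deconvolution output (concentrations 30/8/5/2/
5/10), per-(batch, CpG) chip effects of SD 0.010 and slide effects of SD
0.007, and person-level residual signal s_ij of SD 0.020 — all on the beta
scale, not M-values, matching the beta-scale analysis. Clipping is logged
and stays far below 1% at the defaults because baselines are drawn in
(0.2, 0.8).

Blood pressure is linear in covariates and in the **empirically
standardized** weighted residual sums z_i = standardize(Σ_j w_j s_ij) — the
score a perfect adjustment would recover — so the configured mmHg-per-SD
effects (1.71 SBP, 1.12 DBP for the MRS; 4.83, 2.80 for the GRS) are the
exact estimands of the downstream fits, with no attenuation built in. The
implied per-CpG linkage coefficients (mmHg per beta unit, negative) are
stored in the truth record. Interaction terms use **centered** modifiers
(age standardized; female and college centered at their population
fractions), so the configured main effect remains the average effect that a
no-interaction model estimates, while the interaction coefficients are
directly comparable to fitted ones.

Treatment is assigned by a logistic model on latent (pre-reading-noise)
systolic pressure — slope 0.06 per mmHg — with the intercept calibrated by
root-finding on the realized latent values so the expected treated fraction
hits the 57.7% target; an explicit intercept can be given instead. Treated
participants' readings are **reduced by the same 15/10 mmHg constants the
harmonization step adds back**, so medication adjustment is exercised under
realistic confounding (treatment correlates with underlying pressure) yet
remains unbiased for the latent untreated value. Three readings per trait
add noise of SD 6 (SBP) / 4 (DBP) mmHg; a 0.2% per-reading spike rate
pushes readings past the censoring thresholds. Person-level BP noise (SD
19.5 / 11.0 mmHg) brings the total SDs near the emulated 21.1 / 11.9.

Sampling weights are a documented stand-in — the real weight construction
is not public — generated as exp(0.02·(age − 70.5) + 0.10·female + ε) with
lognormal noise, normalized to mean one.

Seeding: one master seed; stage seeds derive from
`SeedSequence(master).spawn` in the fixed order cohort, methylation,
genotypes, blood pressure, missingness, weights. Identical seed and config
give byte-identical outputs.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (dosages are independent binomials), genome-scale CpG panels, ancestry
structure in the genotypes (labels are random, so PCs carry no population
signal), survey design beyond a scalar weight, and longitudinal structure.
Passing recovery tests therefore demonstrate that the pipeline's estimators
are unbiased and calibrated under the assumed generating model — not that
they are robust to LD, population stratification or informative sampling in
real data.

## Numerical choices and problem sizes

Tolerances: OLS against the normal-equations oracle at 1e-10 on small
instances; adjusted-value mean-zero at 1e-8; cell-fraction row sums at 1e-6
on validated containers (read-time validation warns up to 0.05 before
erroring). Outlier flags use the sample SD (ddof = 1); a zero-SD score
column yields no exclusions. TSV output uses `%.17g` and reading uses
round-trip float parsing, so file round-trips are exact.

The test suite runs its heavy checks at deliberately chosen sizes: one full
pipeline at the emulated cohort size (n = 3070) for single-run effect
recovery; 500 replicates at n = 120 with the true effect zeroed for null
calibration against the exact binomial 99% band; 120 replicates at n = 500
for mean recovery and interval coverage; and n = 2000 with 30 chips for
variance-component recovery within 25%. Replicate-heavy suites bypass the
methylation stage and feed the generator's true standardized scores to the
association models directly — the sampling distribution of the association
estimator does not depend on how the score column was produced, and this
keeps the suites fast enough to run routinely.

## Known limitations

Imputation of missing covariates, longitudinal BP modelling, formal survey
variance (strata/PSU), mixed-effects outcome models, mediation, array-level
preprocessing (probe QC, detection p-values, cell-count deconvolution) and
imputed-dosage handling are out of scope; cell fractions, weights and
ancestry labels are inputs. The per-stratum percentile contrasts depend on
subsample moments, which differ between datasets; the package emits the
moments it used rather than guessing any external ones.
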