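# mrsbp

Methylation and genetic risk scores for blood pressure: a tested, reusable
pipeline from raw per-CpG methylation beta values, genotype dosages and
covariates to harmonized blood-pressure phenotypes, standardized risk
scores, and the association, interaction, heterogeneity and
variance-partition models used to interpret them.

## Who this is for

Epidemiologists and epigenetics researchers who work with cohort data of
the Health and Retirement Study type — older adults with EPIC-array blood
methylation, array genotypes, automated blood-pressure readings and rich
covariates — and who want the full analysis chain as inspectable,
unit-tested code. Because such data are access-restricted, the package
includes a synthetic-cohort generator with known ground truth, so every
stage can be exercised, calibrated and regression-tested without any
download.

## The model

Blood pressure is harmonized from up to three automated readings:
implausible readings are censored (SBP > 250 mmHg, DBP < 40 mmHg), the
survivors averaged, and the standard medication adjustment applied to
participants on antihypertensive treatment:

    SBP = mean(valid SBP readings) + 15 · treated
    DBP = mean(valid DBP readings) + 10 · treated

Each CpG's beta values are cleared of technical and cell-composition
structure by restricted maximum likelihood,

    beta ~ cell fractions (fixed) + chip (random) + slide (random),

and the conditional residuals enter a **methylation risk score** — the
weighted sum over the 13 blood-pressure-associated CpGs with external
EWAS-style weights w_j (mmHg per beta unit, uniformly negative, so a larger
MRS means lower methylation and higher BP):

    MRS_i = Σ_j w_j · adjusted_ij

Scores beyond 5 SD are excluded and the rest standardized; the analogous
**genetic risk score** is the weighted sum of effect-allele dosages,
standardized within ancestry. Association models are ordinary least
squares,

    SBP/DBP ~ score + age + sex + 10 genotype PCs            (Model 1)
    Model 1 + smoking + alcohol + BMI + exercise + diabetes
            + education + parental education                  (Model 2)

with multiplicative score-by-modifier interaction terms (GRS, age, sex,
education dummies), effect-at-level contrasts β_MRS + β_int·z with
delta-method intervals, Cochran's Q across ancestry strata, adjusted-R²
variance partitioning over the covariates/±MRS/±GRS menu on a common
sample, and survey-weighted sensitivity fits with HC1 robust errors.

## Worked example

```python
from mrsbp import (SimulationConfig, simulate_dataset, adjust_matrix,
                   censor_readings, harmonize_bp, compute_mrs, compute_pcs,
                   exclude_outliers, standardize, build_analysis_table,
                   BPModel, ModelSpec)
import pandas as pd

cfg = SimulationConfig(n_participants=2000, seed=7)
d = simulate_dataset(cfg)                      # cohort + omics + truth
adj = adjust_matrix(d["methylation"])          # strip cell/chip/slide structure
bp = harmonize_bp(censor_readings(d["bp_readings"]))
raw = compute_mrs(adj.adjusted, d["cpg_weights"], "sbp")
mrs = standardize(raw, exclude_outliers(raw))
pcs = compute_pcs(d["genotypes"])
table = build_analysis_table(
    d["cohort"], bp,
    pd.DataFrame({"mrs_sbp": mrs.standardized}).rename_axis("id").reset_index(),
    pcs.rename_axis("id").reset_index()).data
fit = BPModel(table, ModelSpec("sbp", ("mrs_sbp",), "model2")).fit()
print(f"MRS_SBP effect: {fit.beta('mrs_sbp'):.2f} mmHg/SD "
      f"(SE {fit.se('mrs_sbp'):.2f}, p {fit.pvalue('mrs_sbp'):.1e}, n {fit.n})")
```

This prints

```
MRS_SBP effect: 1.67 mmHg/SD (SE 0.49, p 6.3e-04, n 1732)
```

— the fully adjusted association between a 1-SD higher methylation risk
score and systolic blood pressure. The generator's true effect is 1.71
mmHg/SD, so the fit recovers it well within one standard error; n drops
from 2000 because the fully adjusted model deletes rows with missing
covariates listwise, exactly as the covariate-missingness rates configure.

The same chain is available from the shell:

```sh
mrsbp run --seed 7 --n 2000 --out results_run
```

which writes every stage's TSV contract (cohort, harmonized BP, adjusted
methylation with variance components, scores, PCs, association /
interaction / heterogeneity / variance-partition tables, prediction grids)
plus a JSON run summary.

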