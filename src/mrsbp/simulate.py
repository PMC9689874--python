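"""Synthetic HRS-like cohort generator with known ground truth.

Every downstream stage of the pipeline — phenotype harmonization, mixed-model
batch adjustment, risk-score construction and the association models — can be
exercised against cohorts produced here, with the generating coefficients
recorded in :class:`SimulationTruth` for recovery tests.

The generator emulates the marginal structure of the study cohort it mimics
(n≈3070 older adults, ~58.5% female, mean age 70.5 y (SD 9.5), ~57.7% on
antihypertensive medication) and the statistical structure the analysis
assumes: methylation beta values with cell-composition loadings, chip and
slide batch variance and per-person residual signal; independent biallelic
SNP dosages; blood pressure that is linear in covariates and in the
standardized true methylation/genetic scores, with optional score-by-modifier
interactions; treatment assigned by a logistic model on latent (pre-noise)
systolic pressure so that medication adjustment is exercised under realistic
confounding.

Seeding: one master seed; per-stage child seeds are derived with
``numpy.random.SeedSequence(master).spawn`` in a fixed documented order
(cohort=0, methylation=1, genotypes=2, blood pressure=3, missingness=4,
weights=5), so stages can be re-run independently and reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "ConfigurationError",
    "simulate_cohort",
    "simulate_methylation",
    "simulate_genotypes",
    "simulate_bp",
    "inject_missingness",
    "simulate_dataset",
    "load_default_cpg_weights",
]

CELL_TYPES = ("Neu", "CD4T", "CD8T", "Bcell", "NK", "Mono")

# Stage indices for SeedSequence.spawn — the documented derivation order.
_STAGES = {"cohort": 0, "methylation": 1, "genotypes": 2, "bp": 3, "missing": 4, "weights": 5}


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return np.random.default_rng(children[_STAGES[stage]])


@dataclass
class SimulationConfig:
    """Tunable parameters of the synthetic cohort.

    Defaults target the marginal characteristics of the emulated cohort
    (age 70.5 ± 9.5 y, 58.5% female, education split 15.5/33.0/51.5%,
    57.7% treated) and score effects on the mmHg-per-SD scale.
    """

    n_participants: int = 3070
    n_cpgs: int = 13
    n_snps: int = 100
    n_chips: int = 16
    slides_per_chip: int = 4
    maf_range: tuple = (0.05, 0.5)
    age_mean: float = 70.5
    age_sd: float = 9.5
    female_fraction: float = 0.585
    # less than high school / high school / at least some college
    education_probs: tuple = (0.155, 0.330, 0.515)
    parental_lt12_prob: float = 0.368
    diabetes_prob: float = 0.282
    # nondrinker / occasional / heavy
    alcohol_probs: tuple = (0.611, 0.325, 0.064)
    # never / former / current
    smoking_probs: tuple = (0.448, 0.445, 0.107)
    exercise_prob: float = 0.558
    bmi_mean: float = 29.9
    bmi_sd: float = 6.2
    ancestry_probs: tuple = (0.658, 0.142, 0.200)  # EA / AA / other
    # logistic treatment model on latent SBP (centered): (intercept, slope).
    # intercept None → calibrated so the expected treated fraction equals
    # treated_fraction_target.
    treatment_model: tuple = (None, 0.06)
    treated_fraction_target: float = 0.577
    # treated participants' readings are reduced by these constants, the same
    # ones the harmonization step adds back
    treatment_reduction_sbp: float = 15.0
    treatment_reduction_dbp: float = 10.0
    cell_fraction_concentrations: tuple = (30.0, 8.0, 5.0, 2.0, 5.0, 10.0)
    cell_loading_sd: float = 0.10  # beta-scale SD of per-CpG cell-type loadings
    batch_sd_chip: float = 0.010
    batch_sd_slide: float = 0.007
    residual_sd_methylation: float = 0.020
    # mmHg-per-SD effects of the true standardized scores
    mrs_effect_sbp: float = 1.71
    mrs_effect_dbp: float = 1.12
    grs_effect_sbp: float = 4.83
    grs_effect_dbp: float = 2.80
    # score-by-modifier interactions, mmHg per SD of MRS per unit of the
    # (centered) modifier: keys "age", "female", "some_college"
    interactions_sbp: dict = field(default_factory=lambda: {"age": -1.19, "female": 0.68, "some_college": 1.31})
    interactions_dbp: dict = field(default_factory=lambda: {"age": -0.74, "female": 0.61, "some_college": 1.08})
    bp_noise_sd_sbp: float = 19.5
    bp_noise_sd_dbp: float = 11.0
    reading_noise_sd_sbp: float = 6.0
    reading_noise_sd_dbp: float = 4.0
    # per-reading probability of an artifactual spike past the censoring
    # thresholds (SBP > 250 or DBP < 40)
    censor_spike_rate: float = 0.002
    missing_rates: dict = field(
        default_factory=lambda: {
            "parental_lt12": 0.062,
            "bmi": 0.050,
            "diabetes": 0.003,
            "alcohol": 0.003,
            "smoking": 0.0003,
            "exercise": 0.005,
        }
    )
    seed: int = 20221027

    def validate(self) -> None:
        for name in ("n_participants", "n_cpgs", "n_snps", "n_chips", "slides_per_chip"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for name in ("female_fraction", "parental_lt12_prob", "diabetes_prob",
                     "exercise_prob", "treated_fraction_target"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("education_probs", "alcohol_probs", "smoking_probs", "ancestry_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-8:
                raise ConfigurationError(f"{name} must be a probability vector summing to 1")
        for name in ("batch_sd_chip", "batch_sd_slide", "residual_sd_methylation",
                     "bp_noise_sd_sbp", "bp_noise_sd_dbp",
                     "reading_noise_sd_sbp", "reading_noise_sd_dbp", "age_sd", "bmi_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if any(a <= 0 for a in self.cell_fraction_concentrations):
            raise ConfigurationError("cell_fraction_concentrations must be positive")
        for k, v in self.missing_rates.items():
            if not 0 <= v <= 1:
                raise ConfigurationError(f"missing rate for {k!r} must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationTruth:
    """Ground-truth coefficients behind one simulated dataset."""

    seed: int
    cpg_ids: list = field(default_factory=list)
    cpg_baseline: np.ndarray | None = None
    cell_loadings: np.ndarray | None = None  # n_cpgs x n_cell_types, beta scale
    cpg_weights: pd.DataFrame | None = None  # the stand-in EWAS weight table
    # implied per-CpG BP linkage, mmHg per beta unit (negative by default)
    cpg_bp_linkage: dict = field(default_factory=dict)
    chip_sd: float = 0.0
    slide_sd: float = 0.0
    residual_sd: float = 0.0
    clipping_rate: float = 0.0
    mrs_effect: dict = field(default_factory=dict)  # trait -> mmHg per SD
    grs_effect: dict = field(default_factory=dict)
    interactions: dict = field(default_factory=dict)  # trait -> modifier -> coef
    covariate_coefs: dict = field(default_factory=dict)  # trait -> name -> coef
    snp_mafs: np.ndarray | None = None
    snp_weights: pd.DataFrame | None = None
    treatment_intercept: float | None = None
    treatment_slope: float | None = None
    # realized standardized true scores (z over the simulated sample)
    true_scores: pd.DataFrame | None = None

    def to_json(self) -> str:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, pd.DataFrame):
                return v.to_dict(orient="list")
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, list):
                return [conv(x) for x in v]
            return v

        return json.dumps({k: conv(v) for k, v in dataclasses.asdict(self).items()}, indent=1)


# covariate effects on blood pressure, mmHg per unit; age per year (centered
# at the configured mean), BMI per kg/m^2 (centered at the configured mean)
_COVARIATE_COEFS = {
    "sbp": {
        "intercept": 138.3, "age": 0.40, "female": -3.0, "bmi": 0.30,
        "diabetes": 3.0, "smoking_former": 1.0, "smoking_current": 3.0,
        "alcohol_occasional": 1.0, "alcohol_heavy": 3.0, "exercise": -2.0,
        "education_hs": -1.0, "education_college": -2.0, "parental_lt12": 1.0,
    },
    "dbp": {
        "intercept": 83.4, "age": -0.15, "female": -2.0, "bmi": 0.20,
        "diabetes": 1.0, "smoking_former": 0.5, "smoking_current": 1.5,
        "alcohol_occasional": 0.5, "alcohol_heavy": 1.5, "exercise": -1.0,
        "education_hs": -0.5, "education_college": -1.0, "parental_lt12": 0.5,
    },
}


def load_default_cpg_weights() -> pd.DataFrame:
    """Synthetic stand-in EWAS weight table for the 13 CpGs (long format)."""
    with resources.files("mrsbp.data").joinpath("weights_cpg_synthetic.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw demographics, behaviors, comorbidities and sampling weights.

    Returns the cohort table and a :class:`SimulationTruth` seeded with the
    covariate coefficients; methylation/genotype/BP stages fill in the rest.
    Raw precursors (drinks per day, glucose, parent years of schooling) are
    generated consistently with the drawn categories so the phenotyping
    operations can re-derive them.
    """
    config.validate()
    rng = _stage_rng(config.seed, "cohort")
    n = config.n_participants

    ids = [f"P{i:06d}" for i in range(1, n + 1)]
    age = rng.normal(config.age_mean, config.age_sd, n).clip(50.5, 102)
    female = (rng.random(n) < config.female_fraction).astype(int)
    education = rng.choice(["lt_hs", "hs", "college"], size=n, p=config.education_probs)
    smoking = rng.choice(["never", "former", "current"], size=n, p=config.smoking_probs)
    alcohol = rng.choice(["nondrinker", "occasional", "heavy"], size=n, p=config.alcohol_probs)
    exercise = (rng.random(n) < config.exercise_prob).astype(int)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, n).clip(15, None)
    ancestry = rng.choice(["EA", "AA", "other"], size=n, p=config.ancestry_probs)
    parental_lt12 = (rng.random(n) < config.parental_lt12_prob).astype(int)
    diabetes = (rng.random(n) < config.diabetes_prob).astype(int)

    # raw precursors consistent with the drawn categories
    limit = np.where(female == 1, 1.0, 2.0)
    drinks = np.zeros(n)
    occ = alcohol == "occasional"
    heavy = alcohol == "heavy"
    drinks[occ] = rng.uniform(0.1, 1.0, occ.sum()) * limit[occ]
    drinks[heavy] = limit[heavy] + rng.exponential(1.0, heavy.sum())

    glucose = rng.uniform(80, 125.9, n)
    hypoglycemic_use = np.zeros(n, dtype=int)
    dia = diabetes == 1
    on_meds = rng.random(n) < 0.5
    hypoglycemic_use[dia & on_meds] = 1
    # medicated diabetics may have controlled glucose; unmedicated ones
    # qualify through the glucose criterion
    glucose[dia & on_meds] = rng.uniform(95, 180, (dia & on_meds).sum())
    glucose[dia & ~on_meds] = 126 + rng.exponential(25, (dia & ~on_meds).sum())

    parent1 = np.where(parental_lt12 == 1, rng.integers(4, 12, n), rng.integers(12, 19, n)).astype(float)
    parent2 = np.where(
        parental_lt12 == 1, rng.integers(4, 12, n), rng.integers(6, 19, n)
    ).astype(float)

    # sampling weight: stand-in for a survey weight — smooth in age and sex
    # plus lognormal noise, normalized to mean 1
    w = np.exp(0.02 * (age - config.age_mean) + 0.10 * female + rng.normal(0, 0.3, n))
    w = w / w.mean()

    cohort = pd.DataFrame(
        {
            "id": ids,
            "age": age,
            "female": female,
            "education": education,
            "high_school": np.isin(education, ["hs", "college"]).astype(int),
            "some_college": (education == "college").astype(int),
            "parent1_years": parent1,
            "parent2_years": parent2,
            "parental_lt12": parental_lt12,
            "bmi": bmi,
            "glucose": glucose,
            "hypoglycemic_use": hypoglycemic_use,
            "diabetes": diabetes,
            "drinks_per_day": drinks,
            "alcohol": alcohol,
            "smoking": smoking,
            "exercise": exercise,
            "ancestry": ancestry,
            "sampling_weight": w,
        }
    ).set_index("id", drop=False)
    cohort.index.name = None

    truth = SimulationTruth(
        seed=config.seed,
        covariate_coefs={t: dict(c) for t, c in _COVARIATE_COEFS.items()},
        mrs_effect={"sbp": config.mrs_effect_sbp, "dbp": config.mrs_effect_dbp},
        grs_effect={"sbp": config.grs_effect_sbp, "dbp": config.grs_effect_dbp},
        interactions={"sbp": dict(config.interactions_sbp), "dbp": dict(config.interactions_dbp)},
        chip_sd=config.batch_sd_chip,
        slide_sd=config.batch_sd_slide,
        residual_sd=config.residual_sd_methylation,
    )
    return cohort, truth


def _draw_cpg_weights(rng: np.random.Generator, cpg_ids: list) -> pd.DataFrame:
    """Negative lognormal-magnitude weights when no fixture applies."""
    rows = []
    for trait in ("sbp", "dbp"):
        w = -np.exp(rng.normal(np.log(15.0), 0.8, len(cpg_ids)))
        rows.append(pd.DataFrame({"feature_id": cpg_ids, "trait": trait, "weight": w}))
    return pd.concat(rows, ignore_index=True)


def simulate_methylation(
    cohort: pd.DataFrame,
    truth: SimulationTruth,
    config: SimulationConfig,
    cpg_weights: pd.DataFrame | None = None,
):
    """Generate beta values with cell-composition, chip/slide and BP-linked
    person-level structure.

    beta_ij = clip(baseline_j + loadings_j · (fractions_i − prior mean)
                   + chip effect + slide effect + s_ij, 0, 1)

    where s_ij ~ N(0, residual_sd²) is the person-specific component that a
    perfect adjustment would recover. The standardized weighted sums
    z_i = standardize(Σ_j w_j s_ij) are recorded in ``truth.true_scores`` and
    drive the blood-pressure stage, so the configured mmHg-per-SD MRS effect
    is the estimand of the downstream fits. The implied per-CpG linkage
    coefficients (mmHg per beta unit) are stored in ``truth.cpg_bp_linkage``.

    Returns a :class:`~mrsbp.adjustment.MethylationMatrix`.
    """
    from .adjustment import MethylationMatrix  # local import to avoid a cycle

    if len(cohort) == 0:
        raise ConfigurationError("cohort is empty")
    rng = _stage_rng(config.seed, "methylation")
    n = len(cohort)
    m = config.n_cpgs

    if cpg_weights is None:
        if m == 13:
            cpg_weights = load_default_cpg_weights()
            cpg_ids = list(cpg_weights["feature_id"].unique())
        else:
            cpg_ids = [f"cpg{j:04d}" for j in range(1, m + 1)]
            cpg_weights = _draw_cpg_weights(rng, cpg_ids)
    else:
        cpg_ids = list(cpg_weights["feature_id"].unique())
        if len(cpg_ids) != m:
            raise ConfigurationError(
                f"weight table has {len(cpg_ids)} CpGs but config.n_cpgs={m}"
            )

    baseline = rng.uniform(0.2, 0.8, m)
    alpha = np.asarray(config.cell_fraction_concentrations, dtype=float)
    prior_mean = alpha / alpha.sum()
    loadings = rng.normal(0.0, config.cell_loading_sd, (m, len(alpha)))

    fractions = rng.dirichlet(alpha, n)

    # round-robin chip assignment, slides nested within chip
    chip_idx = np.arange(n) % config.n_chips
    slide_within = (np.arange(n) // config.n_chips) % config.slides_per_chip
    chip = np.array([f"chip{c:03d}" for c in chip_idx])
    slide = np.array(
        [f"chip{c:03d}_s{s:02d}" for c, s in zip(chip_idx, slide_within)]
    )
    # batch effects are probe-specific: an independent draw per (chip, CpG)
    # and per (slide, CpG)
    chip_eff = rng.normal(0, config.batch_sd_chip, (config.n_chips, m))[chip_idx, :]
    slide_key = chip_idx * config.slides_per_chip + slide_within
    slide_eff = rng.normal(
        0, config.batch_sd_slide, (config.n_chips * config.slides_per_chip, m)
    )[slide_key, :]

    s = rng.normal(0, config.residual_sd_methylation, (n, m))
    raw = (
        baseline[None, :]
        + (fractions - prior_mean) @ loadings.T
        + chip_eff
        + slide_eff
        + s
    )
    betas = np.clip(raw, 0.0, 1.0)
    clip_rate = float(np.mean((raw < 0) | (raw > 1)))
    if clip_rate >= 0.01:
        warnings.warn(f"beta clipping rate {clip_rate:.3%} exceeds 1%", stacklevel=2)

    # true scores: standardized weighted sums of the residual components
    true_scores = {}
    linkage = {}
    for trait in ("sbp", "dbp"):
        wt = (
            cpg_weights.query("trait == @trait")
            .set_index("feature_id")["weight"]
            .reindex(cpg_ids)
        )
        raw_score = s @ wt.to_numpy()
        sd = raw_score.std(ddof=1) if n > 1 else 1.0
        z = (raw_score - raw_score.mean()) / (sd if sd > 0 else 1.0)
        true_scores[f"mrs_{trait}"] = z
        eff = truth.mrs_effect[trait]
        linkage[trait] = dict(zip(cpg_ids, (eff * wt / (sd if sd > 0 else 1.0)).tolist()))

    truth.cpg_ids = cpg_ids
    truth.cpg_baseline = baseline
    truth.cell_loadings = loadings
    truth.cpg_weights = cpg_weights
    truth.cpg_bp_linkage = linkage
    truth.clipping_rate = clip_rate
    ts = pd.DataFrame(true_scores, index=cohort["id"].to_numpy())
    truth.true_scores = ts if truth.true_scores is None else truth.true_scores.join(ts)

    ids = cohort["id"].to_numpy()
    return MethylationMatrix(
        betas=pd.DataFrame(betas, index=ids, columns=cpg_ids),
        chip=pd.Series(chip, index=ids, name="chip"),
        slide=pd.Series(slide, index=ids, name="slide"),
        cell_fractions=pd.DataFrame(fractions, index=ids, columns=list(CELL_TYPES)),
    )


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def simulate_genotypes(cohort: pd.DataFrame, truth: SimulationTruth, config: SimulationConfig):
    """Independent biallelic dosages ~ Binomial(2, MAF), MAFs within
    ``config.maf_range``; SNP weight table with effect alleles, ~20% of them
    on the opposite strand orientation to exercise dosage flipping.

    Returns a :class:`~mrsbp.scores.GenotypeMatrix`.
    """
    from .scores import GenotypeMatrix

    rng = _stage_rng(config.seed, "genotypes")
    n, k = len(cohort), config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], k)
    dosages = rng.binomial(2, mafs, (n, k)).astype(float)
    snp_ids = [f"rs{j + 1:06d}" for j in range(k)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), k)
    counted = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    other = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    flip = rng.random(k) < 0.2
    effect_allele = np.where(flip, other, counted)
    rows = []
    for trait in ("sbp", "dbp"):
        beta = rng.normal(0.0, 0.5, k)
        rows.append(
            pd.DataFrame(
                {"feature_id": snp_ids, "trait": trait, "weight": beta, "effect_allele": effect_allele}
            )
        )
    snp_weights = pd.concat(rows, ignore_index=True)

    ids = cohort["id"].to_numpy()
    geno = GenotypeMatrix(
        dosages=pd.DataFrame(dosages, index=ids, columns=snp_ids),
        counted_allele=pd.Series(counted, index=snp_ids, name="counted_allele"),
    )

    # true standardized GRS: weighted sum of effect-allele-oriented dosages
    true_scores = {}
    for trait in ("sbp", "dbp"):
        wt = snp_weights.query("trait == @trait").set_index("feature_id")
        oriented = np.where(
            wt["effect_allele"].reindex(snp_ids).to_numpy() == counted, dosages, 2.0 - dosages
        )
        raw = oriented @ wt["weight"].reindex(snp_ids).to_numpy()
        sd = raw.std(ddof=1) if n > 1 else 1.0
        true_scores[f"grs_{trait}"] = (raw - raw.mean()) / (sd if sd > 0 else 1.0)

    truth.snp_mafs = mafs
    truth.snp_weights = snp_weights
    ts = pd.DataFrame(true_scores, index=ids)
    truth.true_scores = ts if truth.true_scores is None else truth.true_scores.join(ts)
    return geno


def _linear_predictor(cohort: pd.DataFrame, truth: SimulationTruth, config: SimulationConfig, trait: str):
    c = truth.covariate_coefs[trait]
    lp = np.full(len(cohort), c["intercept"], dtype=float)
    lp += c["age"] * (cohort["age"].to_numpy() - config.age_mean)
    lp += c["female"] * cohort["female"].to_numpy()
    lp += c["bmi"] * (cohort["bmi"].to_numpy() - config.bmi_mean)
    lp += c["diabetes"] * cohort["diabetes"].to_numpy()
    lp += c["smoking_former"] * (cohort["smoking"] == "former").to_numpy()
    lp += c["smoking_current"] * (cohort["smoking"] == "current").to_numpy()
    lp += c["alcohol_occasional"] * (cohort["alcohol"] == "occasional").to_numpy()
    lp += c["alcohol_heavy"] * (cohort["alcohol"] == "heavy").to_numpy()
    lp += c["exercise"] * cohort["exercise"].to_numpy()
    lp += c["education_hs"] * (cohort["education"] == "hs").to_numpy()
    lp += c["education_college"] * (cohort["education"] == "college").to_numpy()
    lp += c["parental_lt12"] * cohort["parental_lt12"].to_numpy()
    return lp


def simulate_bp(
    cohort: pd.DataFrame, truth: SimulationTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent blood pressure, treatment assignment and three noisy readings.

    Latent BP = covariate linear predictor + score effects (using the true
    standardized scores recorded by the methylation/genotype stages) +
    interaction terms on centered modifiers + person-level noise. Treatment
    probability is logistic in latent SBP; treated participants' readings are
    reduced by the medication constants that harmonization later adds back.
    A small per-reading spike rate pushes readings past the censoring
    thresholds to exercise reading-level censoring.

    Returns ``(bp_readings, cohort)`` where the cohort gains the
    ``antihypertensive`` flag.
    """
    rng = _stage_rng(config.seed, "bp")
    n = len(cohort)
    ts = truth.true_scores if truth.true_scores is not None else pd.DataFrame(index=cohort["id"])

    age_std = (cohort["age"].to_numpy() - config.age_mean) / config.age_sd
    modifiers = {
        "age": age_std,
        "female": cohort["female"].to_numpy() - config.female_fraction,
        "some_college": cohort["some_college"].to_numpy() - config.education_probs[2],
        "high_school": cohort["high_school"].to_numpy()
        - (config.education_probs[1] + config.education_probs[2]),
    }

    latent = {}
    for trait in ("sbp", "dbp"):
        lp = _linear_predictor(cohort, truth, config, trait)
        z_mrs = ts.get(f"mrs_{trait}")
        if z_mrs is not None:
            z = z_mrs.reindex(cohort["id"]).to_numpy()
            lp += truth.mrs_effect[trait] * z
            for mod, coef in truth.interactions[trait].items():
                lp += coef * z * modifiers[mod]
        z_grs = ts.get(f"grs_{trait}")
        if z_grs is not None:
            lp += truth.grs_effect[trait] * z_grs.reindex(cohort["id"]).to_numpy()
        noise_sd = config.bp_noise_sd_sbp if trait == "sbp" else config.bp_noise_sd_dbp
        latent[trait] = lp + rng.normal(0, noise_sd, n)

    intercept, slope = config.treatment_model
    centered = latent["sbp"] - latent["sbp"].mean()
    if intercept is None:
        target = config.treated_fraction_target
        if slope == 0:
            intercept = float(np.log(target / (1 - target))) if 0 < target < 1 else (
                np.inf if target >= 1 else -np.inf
            )
        else:
            intercept = brentq(
                lambda a: expit(a + slope * centered).mean() - target, -30, 30
            )
    p_treat = expit(intercept + slope * centered)
    treated = (rng.random(n) < p_treat).astype(int)
    truth.treatment_intercept = float(intercept)
    truth.treatment_slope = float(slope)

    readings = {"id": cohort["id"].to_numpy()}
    for trait, red, rn_sd in (
        ("sbp", config.treatment_reduction_sbp, config.reading_noise_sd_sbp),
        ("dbp", config.treatment_reduction_dbp, config.reading_noise_sd_dbp),
    ):
        base = latent[trait] - red * treated
        for r in (1, 2, 3):
            vals = base + rng.normal(0, rn_sd, n)
            spike = rng.random(n) < config.censor_spike_rate
            if trait == "sbp":
                vals = np.where(spike, rng.uniform(251, 290, n), vals)
            else:
                vals = np.where(spike, rng.uniform(20, 39.9, n), vals)
            readings[f"{trait}{r}"] = vals
    bp = pd.DataFrame(readings)
    bp["antihypertensive"] = treated

    cohort = cohort.copy()
    cohort["antihypertensive"] = treated
    return bp, cohort


def inject_missingness(
    table: pd.DataFrame,
    missing_rates: dict,
    seed: int,
    bp_columns: tuple = ("sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3"),
    min_bp_complete: int = 1,
) -> pd.DataFrame:
    """Mask fields at the configured per-column rates.

    Diabetes missingness is propagated to its raw precursors (glucose and
    medication flag) so re-derivation stays consistent. If masking blood
    pressure would leave fewer than ``min_bp_complete`` rows with at least
    one SBP and one DBP reading, rows are restored at random until the floor
    is met.
    """
    rng = _stage_rng(seed, "missing")
    out = table.copy()
    for col, rate in missing_rates.items():
        if col not in out.columns or rate <= 0:
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
        if col == "diabetes":
            for raw in ("glucose", "hypoglycemic_use"):
                if raw in out.columns:
                    out.loc[mask, raw] = np.nan

    present = [c for c in bp_columns if c in out.columns]
    if present:
        sbp_cols = [c for c in present if c.startswith("sbp")]
        dbp_cols = [c for c in present if c.startswith("dbp")]
        complete = out[sbp_cols].notna().any(axis=1) & out[dbp_cols].notna().any(axis=1)
        deficit = min_bp_complete - int(complete.sum())
        if deficit > 0:
            candidates = out.index[~complete]
            restore = rng.choice(candidates, size=min(deficit, len(candidates)), replace=False)
            out.loc[restore, present] = table.loc[restore, present]
    return out


def simulate_dataset(config: SimulationConfig, cpg_weights: pd.DataFrame | None = None) -> dict:
    """Run all generator stages; returns a dict with ``cohort``,
    ``methylation`` (MethylationMatrix), ``genotypes`` (GenotypeMatrix),
    ``bp_readings``, ``cpg_weights``, ``snp_weights`` and ``truth``."""
    cohort, truth = simulate_cohort(config)
    meth = simulate_methylation(cohort, truth, config, cpg_weights=cpg_weights)
    geno = simulate_genotypes(cohort, truth, config)
    bp, cohort = simulate_bp(cohort, truth, config)
    cohort = inject_missingness(cohort, config.missing_rates, config.seed)
    return {
        "cohort": cohort,
        "methylation": meth,
        "genotypes": geno,
        "bp_readings": bp,
        "cpg_weights": truth.cpg_weights,
        "snp_weights": truth.snp_weights,
        "truth": truth,
    }
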