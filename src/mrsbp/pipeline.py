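"""End-to-end pipeline: simulate → phenotype → adjust → score → associate.

Each stage writes its TSV contract with a provenance header (stage name,
seed, config hash) and the run finishes with a JSON summary of seeds,
sample counts, reference levels and modifier moments. Input files are
resolved before any stage runs (fail fast).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import phenotypes as pheno
from .adjustment import MethylationMatrix, adjust_matrix
from .io import config_hash, read_tsv, validate_inputs, write_tsv
from .scores import GenotypeMatrix, compute_grs, compute_mrs, compute_pcs, exclude_outliers, score_correlation, standardize
from .simulate import SimulationConfig, simulate_dataset
from .specs import MODEL1, MODEL2, ModelSpec

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, stage toggles and analysis constants for one pipeline run."""

    output_dir: str = "mrsbp_output"
    # when simulate=False these inputs must already exist
    simulate: bool = True
    cohort_path: str | None = None
    bp_readings_path: str | None = None
    methylation_path: str | None = None
    cell_fractions_path: str | None = None
    batches_path: str | None = None
    genotypes_path: str | None = None
    weights_cpg_path: str | None = None
    weights_snp_path: str | None = None

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 20221027

    # analysis constants
    sbp_censor_max: float = 250.0
    dbp_censor_min: float = 40.0
    sbp_medication_add: float = 15.0
    dbp_medication_add: float = 10.0
    censor_pairwise: bool = False
    outlier_sd: float = 5.0
    bonferroni_m: int = 13
    alpha: float = 0.05
    n_pcs: int = 10
    strata: tuple = ("EA", "AA")
    run_weighted_sensitivity: bool = True

    def thresholds(self) -> dict:
        return {
            "sbp_censor_max": self.sbp_censor_max,
            "dbp_censor_min": self.dbp_censor_min,
            "sbp_medication_add": self.sbp_medication_add,
            "dbp_medication_add": self.dbp_medication_add,
            "outlier_sd": self.outlier_sd,
            "bonferroni_m": self.bonferroni_m,
            "alpha": self.alpha,
            "n_pcs": self.n_pcs,
        }

    def semantic_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        return d


def _load_inputs(cfg: PipelineConfig):
    paths = {
        "cohort": cfg.cohort_path,
        "bp_readings": cfg.bp_readings_path,
        "methylation": cfg.methylation_path,
        "cell_fractions": cfg.cell_fractions_path,
        "batches": cfg.batches_path,
        "genotypes": cfg.genotypes_path,
        "weights_cpg": cfg.weights_cpg_path,
        "weights_snp": cfg.weights_snp_path,
    }
    missing = [k for k, p in paths.items() if p is None or not Path(p).exists()]
    if missing:
        raise FileNotFoundError(
            "pipeline inputs missing (run with simulate=True or provide them): "
            + ", ".join(missing)
        )
    rep = validate_inputs(paths)
    if not rep.ok:
        raise ValueError("input validation failed:\n" + str(rep))

    cohort = read_tsv(paths["cohort"]).set_index("id", drop=False)
    cohort.index.name = None
    bp = read_tsv(paths["bp_readings"])
    meth_df = read_tsv(paths["methylation"]).set_index("id")
    cf = read_tsv(paths["cell_fractions"]).set_index("id")
    batches = read_tsv(paths["batches"]).set_index("id")
    geno_df = read_tsv(paths["genotypes"]).set_index("id")
    wcpg = read_tsv(paths["weights_cpg"])
    wsnp = read_tsv(paths["weights_snp"])
    meth = MethylationMatrix(
        betas=meth_df,
        chip=batches["chip"].reindex(meth_df.index),
        slide=batches["slide"].reindex(meth_df.index),
        cell_fractions=cf.reindex(meth_df.index),
    )
    counted = (
        wsnp.drop_duplicates("feature_id").set_index("feature_id")["counted_allele"]
        if "counted_allele" in wsnp.columns
        else pd.Series("A", index=geno_df.columns)
    )
    geno = GenotypeMatrix(dosages=geno_df, counted_allele=counted.reindex(geno_df.columns).fillna("A"))
    return {
        "cohort": cohort, "bp_readings": bp, "methylation": meth,
        "genotypes": geno, "cpg_weights": wcpg, "snp_weights": wsnp, "truth": None,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the run summary (also written as JSON)."""
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg.semantic_dict())
    summary: dict = {"seed": cfg.seed, "config_hash": chash, "stages": {}, "thresholds": cfg.thresholds()}

    def emit(df, name, stage):
        write_tsv(df, out / name, stage=stage, seed=cfg.seed, cfg_hash=chash)

    # -- simulate -------------------------------------------------------
    if cfg.simulate:
        cfg.simulation.seed = cfg.seed
        data = simulate_dataset(cfg.simulation)
        meth = data["methylation"]
        emit(data["cohort"], "cohort.tsv", "simulate")
        emit(data["bp_readings"], "bp_readings.tsv", "simulate")
        emit(meth.betas.rename_axis("id").reset_index(), "methylation_beta.tsv", "simulate")
        emit(meth.cell_fractions.rename_axis("id").reset_index(), "cell_fractions.tsv", "simulate")
        emit(
            pd.DataFrame({"id": meth.betas.index, "chip": meth.chip.to_numpy(), "slide": meth.slide.to_numpy()}),
            "batches.tsv", "simulate",
        )
        emit(data["genotypes"].dosages.rename_axis("id").reset_index(), "genotypes.tsv", "simulate")
        emit(data["cpg_weights"], "weights_cpg.tsv", "simulate")
        snp_w = data["snp_weights"].merge(
            data["genotypes"].counted_allele.rename("counted_allele"),
            left_on="feature_id", right_index=True,
        )
        emit(snp_w, "weights_snp.tsv", "simulate")
        (out / "truth.json").write_text(data["truth"].to_json())
        summary["stages"]["simulate"] = {
            "n": len(data["cohort"]),
            "clipping_rate": data["truth"].clipping_rate,
            "treated_fraction": float(data["cohort"]["antihypertensive"].mean()),
        }
    else:
        data = _load_inputs(cfg)
        meth = data["methylation"]

    cohort, bp = data["cohort"], data["bp_readings"]

    # -- phenotype ------------------------------------------------------
    censored = pheno.censor_readings(
        bp, sbp_max=cfg.sbp_censor_max, dbp_min=cfg.dbp_censor_min, pairwise=cfg.censor_pairwise
    )
    harmonized = pheno.harmonize_bp(
        censored, sbp_add=cfg.sbp_medication_add, dbp_add=cfg.dbp_medication_add
    )
    emit(harmonized, "harmonized_bp.tsv", "phenotype")
    summary["stages"]["phenotype"] = {
        "n_bp": int(harmonized["sbp"].notna().sum()),
        "n_censored_sbp": int((3 - harmonized["n_sbp_used"]).sum()),
        "n_censored_dbp": int((3 - harmonized["n_dbp_used"]).sum()),
    }

    # -- adjust ---------------------------------------------------------
    adj = adjust_matrix(meth)
    emit(adj.adjusted.rename_axis("id").reset_index(), "adjusted_methylation.tsv", "adjust")
    emit(adj.variance_components.rename_axis("cpg").reset_index(), "variance_components.tsv", "adjust")
    summary["stages"]["adjust"] = {
        "dropped_cell_column": adj.dropped_cell_column,
        "paths": adj.diagnostics["paths"],
    }

    # -- score ----------------------------------------------------------
    ancestry = cohort["ancestry"]
    score_frames = []
    wide = pd.DataFrame(index=adj.adjusted.index)
    correlations = {}
    for trait in ("sbp", "dbp"):
        raw = compute_mrs(adj.adjusted, data["cpg_weights"], trait)
        flags = exclude_outliers(raw, cfg.outlier_sd)
        mrs = standardize(raw, flags, trait=trait, score_type="mrs")
        grs = compute_grs(
            data["genotypes"], data["snp_weights"], trait,
            ancestry=ancestry.reindex(data["genotypes"].dosages.index),
        )
        wide[f"mrs_{trait}"] = mrs.standardized
        wide[f"grs_{trait}"] = grs.standardized.reindex(wide.index)
        correlations[trait] = score_correlation(mrs, grs)
        for sc in (mrs, grs):
            f = sc.values.rename_axis("id").reset_index()
            f.insert(1, "score_type", sc.score_type)
            f.insert(2, "trait", sc.trait)
            score_frames.append(f)
    emit(pd.concat(score_frames, ignore_index=True), "scores.tsv", "score")
    pcs = compute_pcs(data["genotypes"], n_components=cfg.n_pcs)
    emit(pcs.rename_axis("id").reset_index(), "pcs.tsv", "score")
    summary["stages"]["score"] = {
        "n_outliers": int(sum(f["outlier"].sum() for f in score_frames)),
        "mrs_grs_correlation": correlations,
    }

    # -- associate ------------------------------------------------------
    table = pheno.build_analysis_table(cohort, harmonized, wide.rename_axis("id").reset_index(), pcs.rename_axis("id").reset_index()).data

    def fit_rows(spec_kwargs_list, stage_table=None):
        rows = []
        for kw in spec_kwargs_list:
            spec = ModelSpec(n_pcs=cfg.n_pcs, **kw)
            try:
                fit = assoc.BPModel(stage_table if stage_table is not None else table, spec).fit()
            except assoc.FitError as exc:
                rows.append({**kw, "error": str(exc)})
                continue
            term = fit.primary_term
            rows.append(
                {**kw, "predictors": "+".join(spec.predictors), "term": term,
                 "beta": fit.beta(term), "se": fit.se(term), "p": fit.pvalue(term),
                 "n": fit.n, "adj_r2": fit.rsquared_adj}
            )
        return pd.DataFrame(rows)

    # CpG-level fits (Table-2 shape): per-CpG betas rescaled to per-1%
    cpg_rows = []
    for cpg in adj.adjusted.columns:
        t2 = table.join(adj.adjusted[cpg].rename("cpg_value"), on="id")
        for cs in (MODEL1, MODEL2):
            for outcome in ("sbp", "dbp"):
                spec = ModelSpec(outcome=outcome, predictors=("cpg_value",), covariate_set=cs, n_pcs=cfg.n_pcs)
                try:
                    fit = assoc.BPModel(t2, spec).fit()
                except assoc.FitError as exc:
                    cpg_rows.append({"cpg": cpg, "outcome": outcome, "model": cs, "error": str(exc)})
                    continue
                cpg_rows.append(
                    {"cpg": cpg, "outcome": outcome, "model": cs,
                     "beta_per_1pct": assoc.scale_cpg_effect(fit.beta("cpg_value")),
                     "se_per_1pct": assoc.scale_cpg_effect(fit.se("cpg_value")),
                     "p": fit.pvalue("cpg_value"), "n": fit.n}
                )
    cpg_table = pd.DataFrame(cpg_rows)
    thr = assoc.bonferroni_threshold(cfg.bonferroni_m, cfg.alpha)
    if "p" in cpg_table.columns:
        cpg_table["significant_bonferroni"] = cpg_table["p"] < thr["threshold"]
    emit(cpg_table, "cpg_associations.tsv", "associate")

    # score-level fits (Tables 3-4 shape), full sample and strata
    score_specs = []
    for outcome in ("sbp", "dbp"):
        for cs in (MODEL1, MODEL2):
            for stratum in (None, *cfg.strata):
                score_specs.append(
                    {"outcome": outcome, "predictors": (f"mrs_{outcome}",), "covariate_set": cs, "stratum": stratum}
                )
        for stratum in cfg.strata:  # MRS + GRS, ancestry-specific
            score_specs.append(
                {"outcome": outcome, "predictors": (f"mrs_{outcome}", f"grs_{outcome}"),
                 "covariate_set": MODEL2, "stratum": stratum}
            )
    score_table = fit_rows(score_specs)
    emit(score_table, "score_associations.tsv", "associate")

    # heterogeneity between strata (Cochran's Q) per outcome/model
    het_rows = []
    for outcome in ("sbp", "dbp"):
        for cs in (MODEL1, MODEL2):
            sub = score_table[
                (score_table["outcome"] == outcome)
                & (score_table["covariate_set"] == cs)
                & (score_table["stratum"].notna())
                & (score_table["predictors"] == f"mrs_{outcome}")
            ]
            if len(sub) >= 2 and sub["se"].notna().all():
                het = assoc.cochran_q(list(zip(sub["beta"], sub["se"])), labels=list(sub["stratum"]))
                het_rows.append(
                    {"outcome": outcome, "model": cs, "q": het.q, "df": het.df,
                     "p": het.p, "pooled_beta": het.pooled_beta}
                )
    emit(pd.DataFrame(het_rows), "heterogeneity.tsv", "associate")

    # variance partition per stratum (Table-5 shape)
    vp_frames = []
    for outcome in ("sbp", "dbp"):
        for stratum in cfg.strata:
            spec = ModelSpec(outcome=outcome, predictors=(f"mrs_{outcome}",),
                             covariate_set=MODEL2, stratum=stratum, n_pcs=cfg.n_pcs)
            try:
                vp = assoc.variance_partition(table, spec)
            except assoc.FitError as exc:
                vp = pd.DataFrame([{"model": "covariates", "error": str(exc)}])
            vp.insert(0, "outcome", outcome)
            vp.insert(1, "stratum", stratum)
            vp_frames.append(vp)
    emit(pd.concat(vp_frames, ignore_index=True), "variance_partition.tsv", "associate")

    # interaction models (Table-6 shape) with predicted-value grids
    inter_rows, grid_frames, moments_log = [], [], {}
    for outcome in ("sbp", "dbp"):
        for modifier in ("grs", "age", "female", "high_school", "some_college"):
            for stratum in (None, *cfg.strata) if modifier != "grs" else cfg.strata:
                spec = ModelSpec(
                    outcome=outcome, predictors=(f"mrs_{outcome}",), covariate_set=MODEL2,
                    modifier=modifier, stratum=stratum, n_pcs=cfg.n_pcs,
                )
                try:
                    fit = assoc.BPModel(table, spec).fit()
                except assoc.FitError as exc:
                    inter_rows.append({"outcome": outcome, "modifier": modifier,
                                       "stratum": stratum, "error": str(exc)})
                    continue
                mrs_t, int_t = fit.primary_term, fit.interaction_term
                mod_t = int_t[len(mrs_t) + 3 :]
                inter_rows.append(
                    {"outcome": outcome, "modifier": modifier, "stratum": stratum, "n": fit.n,
                     "beta_mrs": fit.beta(mrs_t), "p_mrs": fit.pvalue(mrs_t),
                     "beta_rf": fit.beta(mod_t), "p_rf": fit.pvalue(mod_t),
                     "beta_interaction": fit.beta(int_t), "p_interaction": fit.pvalue(int_t)}
                )
                if fit.moments:
                    moments_log[f"{outcome}/{modifier}/{stratum or 'full'}"] = {
                        k: {"mean": v[0], "sd": v[1]} for k, v in fit.moments.items()
                    }
                if modifier in ("age", "grs"):
                    raw = fit.moments
                    # grid at the standardized 25th/75th percentiles of the
                    # modifier within the analysis subsample
                    col = "age" if modifier == "age" else f"grs_{outcome}"
                    sub = assoc.BPModel(table, spec).data[col].astype(float)
                    (mean, sd) = list(raw.values())[0]
                    levels = [(sub.quantile(0.25) - mean) / sd, (sub.quantile(0.75) - mean) / sd]
                else:
                    levels = [0.0, 1.0]
                grid = assoc.predicted_grid(fit, levels)
                grid.insert(0, "outcome", outcome)
                grid.insert(1, "modifier", modifier)
                grid.insert(2, "stratum", stratum if stratum else "full")
                grid_frames.append(grid)
    emit(pd.DataFrame(inter_rows), "interactions.tsv", "associate")
    emit(pd.concat(grid_frames, ignore_index=True), "predictions.tsv", "associate")

    if cfg.run_weighted_sensitivity:
        w_specs = []
        for outcome in ("sbp", "dbp"):
            for cs in (MODEL1, MODEL2):
                w_specs.append({"outcome": outcome, "predictors": (f"mrs_{outcome}",),
                                "covariate_set": cs, "weight_column": "sampling_weight"})
        emit(fit_rows(w_specs), "weighted_associations.tsv", "associate")

    def _full_sample_n(cs):
        if "n" not in score_table.columns:
            return None
        sub = score_table[(score_table["covariate_set"] == cs) & score_table["stratum"].isna()]
        return int(sub["n"].iloc[0]) if len(sub) and pd.notna(sub["n"].iloc[0]) else None

    summary["stages"]["associate"] = {
        "n_model1": _full_sample_n(MODEL1),
        "n_model2": _full_sample_n(MODEL2),
        "bonferroni": thr,
        "modifier_moments": moments_log,
        "reference_levels": {"sex": "male", "education": "lt_hs",
                             "smoking": "never", "alcohol": "nondrinker"},
    }
    summary["elapsed_s"] = round(time.time() - t0, 2)
    (out / "run_summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
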