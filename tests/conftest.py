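import numpy as np
import pandas as pd
import pytest

from mrsbp import (
    SimulationConfig,
    adjust_matrix,
    build_analysis_table,
    censor_readings,
    compute_mrs,
    compute_pcs,
    exclude_outliers,
    harmonize_bp,
    simulate_dataset,
    standardize,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_participants=400, n_cpgs=13, n_snps=30, n_chips=8, slides_per_chip=3, seed=101
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_adjusted(small_dataset):
    return adjust_matrix(small_dataset["methylation"])


@pytest.fixture(scope="session")
def small_analysis_table(small_dataset, small_adjusted):
    """Model-ready table built from the session dataset."""
    from mrsbp import compute_grs

    d, adj = small_dataset, small_adjusted
    harmonized = harmonize_bp(censor_readings(d["bp_readings"]))
    pcs = compute_pcs(d["genotypes"])
    ancestry = d["cohort"]["ancestry"]
    wide = pd.DataFrame(index=adj.adjusted.index)
    for trait in ("sbp", "dbp"):
        raw = compute_mrs(adj.adjusted, d["cpg_weights"], trait)
        wide[f"mrs_{trait}"] = standardize(raw, exclude_outliers(raw), trait=trait).standardized
        grs = compute_grs(d["genotypes"], d["snp_weights"], trait,
                          ancestry=ancestry.reindex(adj.adjusted.index))
        wide[f"grs_{trait}"] = grs.standardized.reindex(wide.index)
    return build_analysis_table(
        d["cohort"], harmonized, wide.rename_axis("id").reset_index(),
        pcs.rename_axis("id").reset_index(),
    ).data


def direct_score_table(seed, n=500, mrs_effect_sbp=1.71, mrs_effect_dbp=1.12,
                       interactions_sbp=None, interactions_dbp=None, n_snps=12, n_pcs=2):
    """Fast analysis table that bypasses the methylation stage: the true
    standardized scores from the generator stand in for the computed MRS.

    The association stage's sampling distribution does not depend on how the
    score column was obtained, so replicate-heavy calibration tests use this
    path.
    """
    from mrsbp import simulate_bp, simulate_cohort, simulate_genotypes

    cfg = SimulationConfig(
        n_participants=n, n_snps=n_snps, n_chips=4, slides_per_chip=2, seed=seed,
        mrs_effect_sbp=mrs_effect_sbp, mrs_effect_dbp=mrs_effect_dbp,
        interactions_sbp=interactions_sbp if interactions_sbp is not None else {},
        interactions_dbp=interactions_dbp if interactions_dbp is not None else {},
        missing_rates={},
    )
    cohort, truth = simulate_cohort(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]).generate_state(1)[0])
    z = rng.standard_normal((n, 2))
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
    truth.true_scores = pd.DataFrame(
        {"mrs_sbp": z[:, 0], "mrs_dbp": z[:, 1]}, index=cohort["id"].to_numpy()
    )
    geno = simulate_genotypes(cohort, truth, cfg)
    bp, cohort = simulate_bp(cohort, truth, cfg)
    harmonized = harmonize_bp(censor_readings(bp))
    pcs = compute_pcs(geno, n_components=n_pcs)
    scores = truth.true_scores.drop(columns=[c for c in truth.true_scores if c.startswith("grs")])
    table = build_analysis_table(
        cohort, harmonized, scores.rename_axis("id").reset_index(),
        pcs.rename_axis("id").reset_index(),
    ).data
    return table, truth
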