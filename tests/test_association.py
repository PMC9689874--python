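"""Association models: OLS oracles, heterogeneity, interactions, weighting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrsbp import (
    BPModel,
    ModelSpec,
    adjusted_r2_deltas,
    bonferroni_threshold,
    cochran_q,
    effect_at_level,
    predicted_grid,
    scale_cpg_effect,
    variance_partition,
)
from mrsbp.association import FitError
from mrsbp.specs import SpecError

from conftest import direct_score_table


def _tiny_table(n=8, seed=0, p=2):
    """Small instance with the bare columns a model-1 spec needs."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "id": [f"S{i}" for i in range(n)],
            "sbp": rng.normal(130, 10, n),
            "dbp": rng.normal(80, 5, n),
            "age": rng.normal(70, 8, n),
            "female": rng.integers(0, 2, n).astype(float),
            "mrs_sbp": rng.normal(size=n),
        }
    )
    for i in range(1, p + 1):
        df[f"pc{i}"] = rng.normal(size=n)
    return df


class TestOLS:
    def test_exact_linear_relation_flagged_perfect(self):
        n = 30
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        df = pd.DataFrame({"id": range(n), "sbp": 2 * x + 1, "dbp": 80.0,
                           "age": x, "female": 0.0, "mrs_sbp": x})
        # age == mrs_sbp would be collinear; decouple the design
        df["age"] = rng.normal(size=n)
        df["female"] = rng.integers(0, 2, n).astype(float)
        df["sbp"] = 2 * df["mrs_sbp"] + 1
        fit = BPModel(df, ModelSpec("sbp", ("mrs_sbp",), n_pcs=0)).fit()
        assert fit.beta("mrs_sbp") == pytest.approx(2.0, abs=1e-10)
        assert fit.perfect_fit
        assert fit.se("mrs_sbp") == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        df = _tiny_table(n=12, seed=seed, p=2)
        spec = ModelSpec("sbp", ("mrs_sbp",), n_pcs=2)
        fit = BPModel(df, spec).fit()
        X = np.column_stack([
            np.ones(len(df)), df["mrs_sbp"], df["age"], df["female"], df["pc1"], df["pc2"],
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ df["sbp"].to_numpy())
        assert np.allclose(fit.params["beta"].to_numpy(), beta, atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        df = _tiny_table(n=20, seed=3, p=2)
        df["pc2"] = df["pc1"]
        with pytest.raises(FitError, match="collinear"):
            BPModel(df, ModelSpec("sbp", ("mrs_sbp",), n_pcs=2)).fit()

    def test_too_few_rows_rejected(self):
        df = _tiny_table(n=6, seed=4, p=2)
        with pytest.raises(FitError, match="too small"):
            BPModel(df, ModelSpec("sbp", ("mrs_sbp",), n_pcs=2)).fit()

    def test_recovers_true_effect_within_3_se(self):
        table, truth = direct_score_table(seed=21, n=3000)
        fit = BPModel(table, ModelSpec("sbp", ("mrs_sbp",), "model2", n_pcs=2)).fit()
        assert abs(fit.beta("mrs_sbp") - 1.71) < 3 * fit.se("mrs_sbp")

    def test_effect_recovery_and_ci_coverage_over_replicates(self):
        """Across replicate cohorts the mean fully adjusted MRS coefficient
        sits close to the generating 1.71 mmHg/SD and the 95% interval
        covers it at the nominal rate."""
        truth_eff = 1.71
        est, cover = [], 0
        reps = 120
        spec = ModelSpec("sbp", ("mrs_sbp",), "model2", n_pcs=2)
        for seed in range(reps):
            table, _ = direct_score_table(seed=70000 + seed, n=500)
            fit = BPModel(table, spec).fit()
            b, se = fit.beta("mrs_sbp"), fit.se("mrs_sbp")
            est.append(b)
            t975 = stats.t.ppf(0.975, fit.df_resid)
            if b - t975 * se <= truth_eff <= b + t975 * se:
                cover += 1
        assert abs(np.mean(est) - truth_eff) < 0.1 * max(1.0, truth_eff)
        assert 0.92 <= cover / reps <= 0.975

    def test_summary_mentions_key_quantities(self):
        df = _tiny_table(n=40, seed=5)
        fit = BPModel(df, ModelSpec("sbp", ("mrs_sbp",), n_pcs=2)).fit()
        s = fit.summary()
        assert "SBP" in s and "mrs_sbp" in s and f"n = {fit.n}" in s


class TestScalingAndThresholds:
    def test_cpg_effect_rescaling(self):
        assert scale_cpg_effect(-24.0) == pytest.approx(-0.24)
        assert scale_cpg_effect(0.0) == 0.0

    def test_rescaling_round_trip(self):
        assert scale_cpg_effect(-0.86) / 0.01 == pytest.approx(-0.86)

    @pytest.mark.parametrize(
        "m,alpha,rounded", [(13, 0.05, 0.0038), (1, 0.05, 0.05), (13, 0.0, 0.0)]
    )
    def test_bonferroni(self, m, alpha, rounded):
        out = bonferroni_threshold(m, alpha)
        assert out["rounded"] == pytest.approx(rounded)
        assert out["threshold"] == pytest.approx(alpha / m)


class TestCochranQ:
    def test_identical_estimates_q_zero(self):
        het = cochran_q([(1.5, 0.3), (1.5, 0.3), (1.5, 0.3)])
        assert het.q == pytest.approx(0.0)
        assert het.p == pytest.approx(1.0)
        assert het.df == 2

    def test_hand_computed_extreme_case(self):
        # w = 1 each, pooled = 5, Q = 25 + 25 = 50
        het = cochran_q([(0.0, 1.0), (10.0, 1.0)])
        assert het.pooled_beta == pytest.approx(5.0)
        assert het.q == pytest.approx(50.0)
        assert het.p < 1e-3

    def test_published_style_stratum_pair_is_homogeneous(self):
        # direct-formula oracle: w_EA=1/0.45^2, w_AA=1/1.05^2 -> Q ~= 0.083
        het = cochran_q([(2.11, 0.45), (2.44, 1.05)], labels=["EA", "AA"])
        assert het.q == pytest.approx(0.0834, abs=5e-4)
        assert het.p > 0.05

    def test_scale_invariance(self):
        pairs = [(1.2, 0.4), (0.7, 0.9), (2.0, 0.5)]
        h1 = cochran_q(pairs)
        h2 = cochran_q([(7.3 * b, 7.3 * s) for b, s in pairs])
        assert h1.q == pytest.approx(h2.q, rel=1e-12)
        assert h1.p == pytest.approx(h2.p, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cochran_q([(1.0, 1.0)])
        with pytest.raises(ValueError):
            cochran_q([(1.0, 0.0), (2.0, 1.0)])


class TestEffectAtLevel:
    def test_reference_level_is_main_coefficient_bitwise(self):
        out = effect_at_level(-2.16, 6.36, 0.0)
        assert out.effect == -2.16

    def test_linear_combination(self):
        assert effect_at_level(-2.16, 6.36, 1.0).effect == pytest.approx(4.20)
        assert effect_at_level(0.53, 1.08, 1.0).effect == pytest.approx(1.61)

    def test_se_via_covariance(self):
        out = effect_at_level(1.0, 0.5, 2.0, var_main=0.04, var_interaction=0.01, cov=-0.005)
        assert out.se == pytest.approx(np.sqrt(0.04 + 4 * 0.01 + 2 * 2 * -0.005))
        assert out.ci_low < out.effect < out.ci_high

    def test_fitted_reference_effect_matches_main(self):
        table, _ = direct_score_table(
            seed=3, n=800, interactions_sbp={"female": 2.0}
        )
        spec = ModelSpec("sbp", ("mrs_sbp",), "model2", modifier="female", n_pcs=2)
        fit = BPModel(table, spec).fit()
        assert fit.effect_at_level(0.0).effect == fit.beta("mrs_sbp")


class TestInteractions:
    def test_constant_modifier_clear_error(self):
        table, _ = direct_score_table(seed=4, n=300)
        table["female"] = 1.0
        spec = ModelSpec("sbp", ("mrs_sbp",), "model2", modifier="female", n_pcs=2)
        with pytest.raises(FitError, match="inestimable"):
            BPModel(table, spec).fit()

    def test_modifier_requires_mrs_predictor(self):
        with pytest.raises(SpecError):
            ModelSpec("sbp", ("grs_sbp",), modifier="age")

    def test_generated_interaction_recovered_within_3_se(self):
        table, truth = direct_score_table(
            seed=5, n=3000, interactions_sbp={"age": -1.2}
        )
        spec = ModelSpec("sbp", ("mrs_sbp",), "model2", modifier="age", n_pcs=2)
        fit = BPModel(table, spec).fit()
        term = fit.interaction_term
        assert abs(fit.beta(term) - (-1.2)) < 3 * fit.se(term)
        assert "age" in fit.moments

    def test_null_interaction_rejection_near_alpha(self):
        """With no true interaction the interaction term rejects at roughly
        the nominal 5% level."""
        rej = 0
        reps = 60
        for seed in range(reps):
            table, _ = direct_score_table(seed=3000 + seed, n=250)
            spec = ModelSpec("sbp", ("mrs_sbp",), "model1", modifier="female", n_pcs=2)
            fit = BPModel(table, spec).fit()
            if fit.pvalue(fit.interaction_term) < 0.05:
                rej += 1
        lo, hi = stats.binom.ppf([0.005, 0.995], reps, 0.05)
        assert lo <= rej <= hi


class TestPredictedGrid:
    def _fit(self):
        table, _ = direct_score_table(seed=6, n=1000, interactions_sbp={"female": 3.0})
        spec = ModelSpec("sbp", ("mrs_sbp",), "model2", modifier="female", n_pcs=2)
        return BPModel(table, spec).fit()

    def test_reference_level_line_has_main_effect_slope(self):
        fit = self._fit()
        grid = predicted_grid(fit, [0.0], score_range=(0.0, 1.0), n_points=2)
        slope = grid["predicted"].diff().iloc[-1]
        assert slope == pytest.approx(fit.beta("mrs_sbp"), abs=1e-10)

    def test_slope_gap_equals_interaction_times_level_gap(self):
        fit = self._fit()
        z25, z75 = 0.0, 1.0
        grid = predicted_grid(fit, [z25, z75], score_range=(0.0, 1.0), n_points=2)
        slopes = grid.groupby("modifier_level")["predicted"].agg(lambda s: s.iloc[1] - s.iloc[0])
        gap = slopes[z75] - slopes[z25]
        assert gap == pytest.approx(fit.beta(fit.interaction_term) * (z75 - z25), abs=1e-10)

    def test_monotone_when_effect_positive(self):
        fit = self._fit()
        lvl = 1.0 if fit.effect_at_level(1.0).effect > 0 else 0.0
        grid = predicted_grid(fit, [lvl], score_range=(-2, 2), n_points=9)
        assert grid["predicted"].is_monotonic_increasing or grid["predicted"].is_monotonic_decreasing


class TestWeightedFits:
    def test_equal_weights_match_ols(self):
        table, _ = direct_score_table(seed=7, n=500)
        table["sampling_weight"] = 2.5
        ols = BPModel(table, ModelSpec("sbp", ("mrs_sbp",), "model1", n_pcs=2)).fit()
        wls = BPModel(
            table, ModelSpec("sbp", ("mrs_sbp",), "model1", weight_column="sampling_weight", n_pcs=2)
        ).fit()
        assert np.allclose(ols.params["beta"], wls.params["beta"], atol=1e-10)

    def test_duplicating_row_equals_doubling_weight(self):
        table, _ = direct_score_table(seed=8, n=300)
        table = table.reset_index(drop=True)
        table["sampling_weight"] = 1.0
        dup = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        doubled = table.copy()
        doubled.loc[0, "sampling_weight"] = 2.0
        spec = ModelSpec("sbp", ("mrs_sbp",), "model1", weight_column="sampling_weight", n_pcs=2)
        f_dup = BPModel(dup, spec).fit()
        f_dbl = BPModel(doubled, spec).fit()
        assert np.allclose(f_dup.params["beta"], f_dbl.params["beta"], atol=1e-10)

    def test_robust_ses_finite_positive(self):
        table, _ = direct_score_table(seed=9, n=400)
        spec = ModelSpec("sbp", ("mrs_sbp",), "model2", weight_column="sampling_weight", n_pcs=2)
        fit = BPModel(table, spec).fit()
        assert (fit.params["se"] > 0).all()
        assert np.isfinite(fit.params["se"]).all()


class TestVariancePartition:
    def test_menu_shares_common_sample(self, small_analysis_table):
        spec = ModelSpec("sbp", ("mrs_sbp",), "model2", n_pcs=2)
        vp = variance_partition(small_analysis_table, spec)
        assert vp["n"].nunique() == 1
        assert set(vp["model"]) == {
            "covariates", "covariates+mrs", "covariates+grs", "covariates+mrs+grs"
        }

    def test_delta_arithmetic_on_given_menu(self):
        menu = {"covariates": 8.5, "covariates+mrs": 10.3,
                "covariates+grs": 11.7, "covariates+mrs+grs": 12.1}
        deltas = adjusted_r2_deltas(menu)
        assert deltas["covariates+mrs+grs - covariates"] == pytest.approx(3.6)
        assert deltas["covariates+mrs+grs - covariates+grs"] == pytest.approx(0.4)

    def test_unrelated_score_adds_nothing_at_scale(self):
        table, _ = direct_score_table(seed=10, n=2500, mrs_effect_sbp=0.0, mrs_effect_dbp=0.0)
        rng = np.random.default_rng(0)
        table["grs_sbp"] = rng.standard_normal(len(table))
        spec = ModelSpec("sbp", ("mrs_sbp",), "model1", n_pcs=2)
        vp = variance_partition(table, spec)
        base = vp.loc[vp["model"] == "covariates", "adj_r2"].iloc[0]
        full = vp.loc[vp["model"] == "covariates+mrs+grs", "adj_r2"].iloc[0]
        assert abs(full - base) < 0.01

    def test_pure_noise_column_can_lower_adjusted_r2(self):
        table, _ = direct_score_table(seed=11, n=2000, mrs_effect_sbp=0.0, mrs_effect_dbp=0.0)
        rng = np.random.default_rng(1)
        table["grs_sbp"] = rng.standard_normal(len(table))
        spec = ModelSpec("sbp", ("mrs_sbp",), "model1", n_pcs=2)
        vp = variance_partition(table, spec).set_index("model")
        assert (
            vp.loc["covariates+mrs+grs", "adj_r2"] < vp.loc["covariates", "adj_r2"]
            or vp.loc["covariates+mrs", "adj_r2"] < vp.loc["covariates", "adj_r2"]
            or vp.loc["covariates+grs", "adj_r2"] < vp.loc["covariates", "adj_r2"]
        )
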