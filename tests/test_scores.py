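"""Risk-score construction: linearity, orientation, outliers, PCs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsbp import (
    GenotypeMatrix,
    compute_grs,
    compute_mrs,
    compute_pcs,
    exclude_outliers,
    score_correlation,
    standardize,
)
from mrsbp.scores import ScoreError


def _weights(wd: dict, trait="sbp", effect_allele=None):
    df = pd.DataFrame({"feature_id": list(wd), "trait": trait, "weight": list(wd.values())})
    if effect_allele is not None:
        df["effect_allele"] = effect_allele
    return df


class TestMRS:
    def test_zero_weights_zero_scores(self):
        adj = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)), columns=["a", "b"])
        raw = compute_mrs(adj, _weights({"a": 0.0, "b": 0.0}), "sbp")
        assert (raw == 0).all()

    def test_negative_weights_rank_low_methylation_higher(self):
        """With uniformly negative weights the lower-methylation row gets the
        larger score — the coding where a larger MRS means higher BP."""
        adj = pd.DataFrame([[0.1, 0.1], [-0.1, -0.1]], index=["A", "B"], columns=["a", "b"])
        raw = compute_mrs(adj, _weights({"a": -1.0, "b": -1.0}), "sbp")
        assert raw["A"] == pytest.approx(-0.2)
        assert raw["B"] == pytest.approx(0.2)
        assert raw["B"] > raw["A"]

    def test_linear_in_weights(self):
        rng = np.random.default_rng(1)
        adj = pd.DataFrame(rng.normal(size=(8, 3)), columns=["a", "b", "c"])
        w1 = {"a": -2.0, "b": 1.0, "c": 0.5}
        w2 = {"a": 0.3, "b": -0.7, "c": 4.0}
        wsum = {k: w1[k] + w2[k] for k in w1}
        s = compute_mrs(adj, _weights(wsum), "sbp")
        s12 = compute_mrs(adj, _weights(w1), "sbp") + compute_mrs(adj, _weights(w2), "sbp")
        assert np.allclose(s, s12)

    def test_missing_cpg_listed_in_error(self):
        adj = pd.DataFrame(np.zeros((3, 1)), columns=["a"])
        with pytest.raises(ScoreError, match="ghost"):
            compute_mrs(adj, _weights({"a": 1.0, "ghost": 2.0}), "sbp")

    def test_absent_trait_is_configuration_error(self):
        adj = pd.DataFrame(np.zeros((3, 1)), columns=["a"])
        with pytest.raises(ScoreError, match="dbp"):
            compute_mrs(adj, _weights({"a": 1.0}, trait="sbp"), "dbp")

    def test_orientation_anticorrelates_with_mean_methylation(self, small_adjusted, small_dataset):
        """Standardized MRS built from all-negative weights correlates
        negatively with the unweighted mean of adjusted methylation."""
        adj = small_adjusted.adjusted
        w = small_dataset["cpg_weights"]
        assert (w["weight"] < 0).all()
        raw = compute_mrs(adj, w, "sbp")
        z = standardize(raw).standardized
        r = np.corrcoef(z, adj.mean(axis=1))[0, 1]
        assert r < 0


class TestOutliers:
    def test_six_sd_point_flagged(self):
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(0, 1, 500))
        x.iloc[0] = x.mean() + 8 * x.std()
        flags = exclude_outliers(x, k=5)
        assert flags.iloc[0]
        assert flags.sum() == 1

    def test_constant_column_no_exclusions(self):
        flags = exclude_outliers(pd.Series([3.0] * 10), k=5)
        assert not flags.any()

    def test_infinite_k_no_exclusions(self):
        x = pd.Series(np.random.default_rng(3).normal(0, 1, 50))
        assert not exclude_outliers(x, k=np.inf).any()

    def test_outlier_excluded_from_moments_but_reported(self):
        x = pd.Series(np.concatenate([np.random.default_rng(4).normal(0, 1, 400), [60.0]]))
        flags = exclude_outliers(x, k=5)
        assert flags.iloc[-1]
        rs = standardize(x, flags)
        keep = x[~flags]
        expected = (keep - keep.mean()) / keep.std(ddof=1)
        assert np.allclose(rs.standardized[~flags], expected)
        assert np.isnan(rs.standardized.iloc[-1])
        assert rs.values["outlier"].iloc[-1]


class TestStandardize:
    def test_simple_arithmetic(self):
        rs = standardize(pd.Series([1.0, 2.0, 3.0]))
        assert np.allclose(rs.standardized, [-1.0, 0.0, 1.0])

    def test_moments_within_tolerance(self, small_adjusted, small_dataset):
        raw = compute_mrs(small_adjusted.adjusted, small_dataset["cpg_weights"], "dbp")
        z = standardize(raw, exclude_outliers(raw)).standardized.dropna()
        assert abs(z.mean()) < 1e-8
        assert abs(z.std(ddof=1) - 1.0) < 1e-8

    def test_groupwise_standardization_independent(self):
        x = pd.Series(np.arange(10, dtype=float))
        g = pd.Series(["a"] * 5 + ["b"] * 5)
        rs = standardize(x, groups=g)
        for lab in ("a", "b"):
            sub = rs.standardized[g == lab]
            assert abs(sub.mean()) < 1e-12
            assert abs(sub.std(ddof=1) - 1) < 1e-12

    def test_tiny_group_rejected(self):
        with pytest.raises(ScoreError, match="fewer than 2"):
            standardize(pd.Series([1.0, 2.0, 3.0]), groups=pd.Series(["a", "a", "b"]))

    def test_idempotent_on_standardized_input(self):
        x = pd.Series(np.random.default_rng(5).normal(size=200))
        z1 = standardize(x).standardized
        z2 = standardize(z1).standardized
        assert np.allclose(z1, z2, atol=1e-12)


class TestGRS:
    def _geno(self, dosages, counted="A"):
        df = pd.DataFrame({"snp1": dosages}, index=[f"S{i}" for i in range(len(dosages))])
        return GenotypeMatrix(df, pd.Series([counted], index=["snp1"]))

    def test_single_snp_identity(self):
        g = self._geno([0.0, 1.0, 2.0])
        rs = compute_grs(g, _weights({"snp1": 1.0}, effect_allele=["A"]), "sbp")
        assert np.allclose(rs.raw, [0, 1, 2])

    def test_allele_flip_reverses_dosage(self):
        g = self._geno([0.0, 1.0, 2.0])
        rs = compute_grs(g, _weights({"snp1": 1.0}, effect_allele=["G"]), "sbp")
        assert np.allclose(rs.raw, [2, 1, 0])

    def test_flip_plus_negated_weight_equals_original_up_to_constant(self):
        rng = np.random.default_rng(6)
        d = pd.DataFrame(rng.binomial(2, 0.3, (50, 2)).astype(float), columns=["s1", "s2"])
        geno = GenotypeMatrix(d, pd.Series(["A", "A"], index=["s1", "s2"]))
        w1 = _weights({"s1": 0.8, "s2": -0.3}, effect_allele=["A", "A"])
        w2 = _weights({"s1": -0.8, "s2": -0.3}, effect_allele=["G", "A"])
        r1 = compute_grs(geno, w1, "sbp")
        r2 = compute_grs(geno, w2, "sbp")
        diff = r1.raw - r2.raw
        assert np.allclose(diff, diff.iloc[0])
        assert np.allclose(r1.standardized, r2.standardized, atol=1e-12)

    def test_within_ancestry_means_zero(self):
        rng = np.random.default_rng(7)
        d = pd.DataFrame(rng.binomial(2, 0.4, (60, 3)).astype(float),
                         columns=["s1", "s2", "s3"],
                         index=[f"S{i}" for i in range(60)])
        geno = GenotypeMatrix(d, pd.Series(["A"] * 3, index=d.columns))
        anc = pd.Series(["EA"] * 30 + ["AA"] * 30, index=d.index)
        rs = compute_grs(geno, _weights({"s1": 1.0, "s2": -0.5, "s3": 0.2},
                                        effect_allele=["A", "A", "A"]), "sbp", ancestry=anc)
        for lab in ("EA", "AA"):
            assert abs(rs.standardized[anc == lab].mean()) < 1e-10


class TestPCs:
    def test_too_few_snps_rejected(self):
        d = pd.DataFrame(np.random.default_rng(8).binomial(2, 0.3, (30, 5)).astype(float))
        d.columns = [f"s{i}" for i in range(5)]
        geno = GenotypeMatrix(d, pd.Series(["A"] * 5, index=d.columns))
        with pytest.raises(ScoreError, match="at least 10"):
            compute_pcs(geno)

    def test_duplicated_samples_share_coordinates(self):
        rng = np.random.default_rng(9)
        d = pd.DataFrame(rng.binomial(2, 0.3, (40, 12)).astype(float),
                         columns=[f"s{i}" for i in range(12)])
        d.iloc[1] = d.iloc[0]
        geno = GenotypeMatrix(d, pd.Series(["A"] * 12, index=d.columns))
        pcs = compute_pcs(geno, n_components=3)
        assert np.allclose(pcs.iloc[0], pcs.iloc[1], atol=1e-10)

    def test_two_cluster_structure_separated_by_pc1(self):
        rng = np.random.default_rng(10)
        n_half, k = 60, 20
        a = rng.binomial(2, 0.15, (n_half, k)).astype(float)
        b = rng.binomial(2, 0.85, (n_half, k)).astype(float)
        d = pd.DataFrame(np.vstack([a, b]), columns=[f"s{i}" for i in range(k)])
        geno = GenotypeMatrix(d, pd.Series(["A"] * k, index=d.columns))
        pc1 = compute_pcs(geno, n_components=10)["pc1"]
        labels = np.array([0] * n_half + [1] * n_half)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(pc1.to_numpy().reshape(-1, 1), labels) > 0

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(11)
        d = pd.DataFrame(rng.binomial(2, 0.4, (50, 15)).astype(float),
                         columns=[f"s{i}" for i in range(15)])
        geno = GenotypeMatrix(d, pd.Series(["A"] * 15, index=d.columns))
        p1 = compute_pcs(geno, n_components=4)
        p2 = compute_pcs(geno, n_components=4)
        pd.testing.assert_frame_equal(p1, p2)


class TestCorrelation:
    def test_self_correlation_is_one(self, small_adjusted, small_dataset):
        raw = compute_mrs(small_adjusted.adjusted, small_dataset["cpg_weights"], "sbp")
        rs = standardize(raw)
        out = score_correlation(rs, rs)
        assert out["r"] == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(12)
        a = pd.Series(rng.normal(size=300))
        b = pd.Series(0.3 * a + rng.normal(size=300))
        r1 = score_correlation(standardize(a), standardize(b))["r"]
        r2 = score_correlation(standardize(5 * a + 2), standardize(-1 * b))["r"]
        assert r1 == pytest.approx(abs(r2), abs=1e-12)

    def test_independent_scores_near_zero(self):
        """Null-correlation band: independent scores at n=2000 stay within
        |r| < 0.07 for the vast majority of seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            a = standardize(pd.Series(rng.normal(size=2000)))
            b = standardize(pd.Series(rng.normal(size=2000)))
            if abs(score_correlation(a, b)["r"]) < 0.07:
                hits += 1
        assert hits >= 19
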