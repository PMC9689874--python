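"""Methylation and genetic risk scores plus genotype principal components.

An MRS is the weighted sum of batch/cell-adjusted methylation residuals over
trait-associated CpGs, using externally supplied (EWAS-style) weights on the
mmHg-per-beta-unit scale; with uniformly negative weights a larger score
reflects lower overall methylation and higher blood pressure. A GRS is the
weighted sum of effect-allele dosages over genotyped SNPs. Scores beyond
five SDs of the mean are flagged as outliers and excluded before
standardization; the MRS is standardized over the whole analytic sample by
default while the GRS is standardized within ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "GenotypeMatrix",
    "RiskScore",
    "ScoreError",
    "compute_mrs",
    "exclude_outliers",
    "standardize",
    "compute_grs",
    "compute_pcs",
    "score_correlation",
]

OUTLIER_SD_MULTIPLE = 5.0


class ScoreError(ValueError):
    """Score construction failed (missing features, degenerate groups...)."""


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x SNPs, values in {0,1,2} or fractional) with
    the allele each dosage column counts."""

    dosages: pd.DataFrame
    counted_allele: pd.Series  # indexed by SNP id

    def validate(self) -> None:
        d = self.dosages.to_numpy()
        if np.nanmin(d) < 0 or np.nanmax(d) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        missing = [s for s in self.dosages.columns if s not in self.counted_allele.index]
        if missing:
            raise ValueError(f"no counted allele recorded for SNP(s): {missing[:5]}")


@dataclass
class RiskScore:
    """Per-sample raw and standardized score with outlier mask."""

    values: pd.DataFrame  # columns: raw, standardized, outlier, group
    trait: str
    score_type: str  # "mrs" or "grs"
    standardization: str  # "whole-sample" or "within-ancestry"

    @property
    def standardized(self) -> pd.Series:
        return self.values["standardized"]

    @property
    def raw(self) -> pd.Series:
        return self.values["raw"]


def _trait_weights(weights: pd.DataFrame, trait: str) -> pd.DataFrame:
    if trait not in set(weights["trait"]):
        raise ScoreError(f"trait {trait!r} absent from weight table")
    wt = weights[weights["trait"] == trait]
    if wt["feature_id"].duplicated().any():
        dups = wt.loc[wt["feature_id"].duplicated(), "feature_id"].tolist()
        raise ScoreError(f"duplicate weights for feature(s): {dups}")
    return wt.set_index("feature_id")


def compute_mrs(adjusted: pd.DataFrame, weights: pd.DataFrame, trait: str) -> pd.Series:
    """Raw methylation risk score: score_i = sum_j w_j * adjusted_ij.

    ``adjusted`` is the samples x CpGs residual matrix; ``weights`` a long
    table with columns feature_id / trait / weight. Every weighted CpG must
    be present.
    """
    wt = _trait_weights(weights, trait)
    missing = [c for c in wt.index if c not in adjusted.columns]
    if missing:
        raise ScoreError(f"adjusted matrix lacks weighted CpG(s): {missing}")
    raw = adjusted[list(wt.index)].to_numpy() @ wt["weight"].to_numpy()
    return pd.Series(raw, index=adjusted.index, name=f"mrs_{trait}_raw")


def exclude_outliers(raw: pd.Series, k: float = OUTLIER_SD_MULTIPLE) -> pd.Series:
    """Flag values more than ``k`` sample SDs from the mean (moments over all
    raw scores). A zero-SD column yields no exclusions."""
    x = raw.to_numpy(dtype=float)
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if sd == 0 or not np.isfinite(k):
        flags = np.zeros(len(x), dtype=bool)
    else:
        flags = np.abs(x - x.mean()) > k * sd
    return pd.Series(flags, index=raw.index, name="outlier")


def standardize(
    raw: pd.Series,
    outlier_flags: pd.Series | None = None,
    groups: pd.Series | None = None,
    trait: str = "",
    score_type: str = "mrs",
) -> RiskScore:
    """Z-score using the mean/SD of the non-outlier set, within each
    standardization group when ``groups`` is given. Flagged samples keep a
    missing standardized value."""
    if outlier_flags is None:
        outlier_flags = pd.Series(False, index=raw.index)
    values = pd.DataFrame({"raw": raw, "outlier": outlier_flags.astype(bool)})
    values["group"] = "all" if groups is None else groups.reindex(raw.index)
    z = pd.Series(np.nan, index=raw.index, dtype=float)
    for g, sub in values.groupby("group", observed=True):
        keep = sub.loc[~sub["outlier"], "raw"]
        if len(keep) < 2:
            raise ScoreError(f"standardization group {g!r} has fewer than 2 non-outliers")
        sd = keep.std(ddof=1)
        if sd == 0:
            raise ScoreError(f"standardization group {g!r} has zero variance")
        z.loc[keep.index] = (keep - keep.mean()) / sd
    values["standardized"] = z
    return RiskScore(
        values=values,
        trait=trait,
        score_type=score_type,
        standardization="whole-sample" if groups is None else "within-ancestry",
    )


def compute_grs(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    trait: str,
    ancestry: pd.Series | None = None,
    outlier_k: float = np.inf,
) -> RiskScore:
    """Genetic risk score: weighted sum of dosages oriented to each weight's
    effect allele (mismatched orientations are flipped, dosage -> 2 - dosage),
    standardized within ancestry when labels are given."""
    genotypes.validate()
    wt = _trait_weights(weights, trait)
    missing = [s for s in wt.index if s not in genotypes.dosages.columns]
    if missing:
        raise ScoreError(f"genotype matrix lacks weighted SNP(s): {missing[:5]}")
    snps = list(wt.index)
    D = genotypes.dosages[snps].to_numpy(dtype=float)
    if "effect_allele" in wt.columns:
        counted = genotypes.counted_allele.reindex(snps).to_numpy()
        flip = wt["effect_allele"].to_numpy() != counted
        D = np.where(flip[None, :], 2.0 - D, D)
    raw = pd.Series(D @ wt["weight"].to_numpy(), index=genotypes.dosages.index,
                    name=f"grs_{trait}_raw")
    flags = exclude_outliers(raw, outlier_k)
    return standardize(raw, flags, groups=ancestry, trait=trait, score_type="grs")


def compute_pcs(genotypes: GenotypeMatrix, n_components: int = 10) -> pd.DataFrame:
    """Top principal components of the column-standardized dosage matrix.

    Monomorphic SNPs are dropped before standardization. Column signs are
    fixed so the largest-magnitude loading of each component is positive.
    Returns a samples x ``n_components`` frame with columns ``pc1..pcN``.
    """
    D = genotypes.dosages
    keep = D.columns[D.std(ddof=0) > 0]
    if len(keep) < n_components:
        raise ScoreError(
            f"need at least {n_components} polymorphic SNPs for {n_components} PCs, have {len(keep)}"
        )
    X = D[keep].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    # deterministic sign convention
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    return pd.DataFrame(
        coords, index=D.index, columns=[f"pc{i}" for i in range(1, n_components + 1)]
    )


def score_correlation(mrs: RiskScore, grs: RiskScore) -> dict:
    """Pearson correlation between two standardized scores on the samples
    holding both."""
    a = mrs.standardized
    b = grs.standardized.reindex(a.index)
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ScoreError("fewer than 3 samples with both scores")
    r, p = stats.pearsonr(a[ok], b[ok])
    return {"r": float(r), "p": float(p), "n": int(ok.sum())}
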