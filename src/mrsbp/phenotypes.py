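"""Blood-pressure harmonization and covariate coding.

Readings are censored per trait and per reading (SBP > 250 mmHg and
DBP < 40 mmHg removed, boundary values kept), the surviving readings are
averaged, and fixed medication constants (+15 mmHg SBP, +10 mmHg DBP) are
added for participants on antihypertensive medication — the standard
approximation of the untreated blood pressure. Covariate coders implement
the glucose/medication diabetes definition, sex-specific drinking
categories, and the all-parents-below-12-years parental-education dichotomy
with its categorical legacy-cohort input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "censor_readings",
    "harmonize_bp",
    "classify_diabetes",
    "categorize_alcohol",
    "dichotomize_parental_education",
    "build_analysis_table",
    "AnalysisTable",
    "SchemaError",
    "EmptyTableError",
]

SBP_CENSOR_MAX = 250.0
DBP_CENSOR_MIN = 40.0
SBP_MEDICATION_ADD = 15.0
DBP_MEDICATION_ADD = 10.0
GLUCOSE_CUTOFF = 126.0

_SBP_COLS = ("sbp1", "sbp2", "sbp3")
_DBP_COLS = ("dbp1", "dbp2", "dbp3")


class SchemaError(KeyError):
    """A required column is absent."""


class EmptyTableError(ValueError):
    """A join or deletion produced an empty table."""


def censor_readings(
    readings: pd.DataFrame,
    sbp_max: float = SBP_CENSOR_MAX,
    dbp_min: float = DBP_CENSOR_MIN,
    pairwise: bool = False,
) -> pd.DataFrame:
    """Remove implausible readings: SBP values strictly above ``sbp_max`` and
    DBP values strictly below ``dbp_min``. Boundary values are kept.

    Censoring is trait-wise by default — an SBP value can be dropped while
    its paired DBP reading is kept. ``pairwise=True`` drops both members of
    an offending pair.
    """
    out = readings.copy()
    for i, (sc, dc) in enumerate(zip(_SBP_COLS, _DBP_COLS), start=1):
        s_bad = out[sc] > sbp_max if sc in out else pd.Series(False, index=out.index)
        d_bad = out[dc] < dbp_min if dc in out else pd.Series(False, index=out.index)
        if pairwise:
            bad = s_bad | d_bad
            s_bad = d_bad = bad
        if sc in out:
            out.loc[s_bad, sc] = np.nan
        if dc in out:
            out.loc[d_bad, dc] = np.nan
    return out


def harmonize_bp(
    readings: pd.DataFrame,
    sbp_add: float = SBP_MEDICATION_ADD,
    dbp_add: float = DBP_MEDICATION_ADD,
) -> pd.DataFrame:
    """Average the (already censored) readings and apply the medication
    adjustment after averaging.

    Expects columns ``sbp1..3``, ``dbp1..3`` and ``antihypertensive``.
    Returns a frame with ``sbp``, ``dbp``, ``n_sbp_used``, ``n_dbp_used``
    and ``medication_adjusted``; participants with no surviving readings get
    a missing harmonized value.
    """
    for col in ("antihypertensive",):
        if col not in readings.columns:
            raise SchemaError(col)
    sbp_cols = [c for c in _SBP_COLS if c in readings.columns]
    dbp_cols = [c for c in _DBP_COLS if c in readings.columns]
    if not sbp_cols and not dbp_cols:
        raise SchemaError("sbp1/dbp1")

    out = pd.DataFrame(index=readings.index)
    if "id" in readings.columns:
        out["id"] = readings["id"]
    flag = readings["antihypertensive"].astype(float)

    sbp_mean = readings[sbp_cols].mean(axis=1, skipna=True)
    dbp_mean = readings[dbp_cols].mean(axis=1, skipna=True)
    out["n_sbp_used"] = readings[sbp_cols].notna().sum(axis=1).astype(int)
    out["n_dbp_used"] = readings[dbp_cols].notna().sum(axis=1).astype(int)
    out["sbp"] = sbp_mean + sbp_add * flag
    out["dbp"] = dbp_mean + dbp_add * flag
    out["medication_adjusted"] = flag.fillna(0).astype(int)
    out["antihypertensive"] = readings["antihypertensive"]
    return out


def classify_diabetes(glucose, hypoglycemic_or_insulin_use, cutoff: float = GLUCOSE_CUTOFF):
    """Type-2 diabetes flag: medication use, or glucose at or above the
    cutoff (mg/dL, inclusive). Vectorized; missing on both inputs → missing."""
    g = pd.Series(np.asarray(glucose, dtype=float))
    meds = pd.Series(np.asarray(hypoglycemic_or_insulin_use, dtype=float))
    yes = (meds == 1) | (g >= cutoff)  # NaN comparisons are False
    no = (meds == 0) & (g < cutoff)
    out = pd.Series(np.where(yes, 1.0, np.where(no, 0.0, np.nan)))
    return out


def categorize_alcohol(drinks_per_day, female, female_limit: float = 1.0, male_limit: float = 2.0):
    """Nondrinker / occasional / heavy, with sex-specific daily-drink bounds
    (occasional means at most 1 drink/day for females, 2 for males)."""
    d = pd.Series(np.asarray(drinks_per_day, dtype=float))
    f = pd.Series(np.asarray(female, dtype=float)).reset_index(drop=True)
    limit = np.where(f == 1, female_limit, male_limit)
    out = pd.Series(np.where(d == 0, "nondrinker", np.where(d <= limit, "occasional", "heavy")))
    out[d.isna() | f.isna()] = np.nan
    return out


def dichotomize_parental_education(parent_years, ahead_category=None):
    """Flag: 1 if every parent with reported schooling had under 12 years,
    0 if at least one parent reached 12 years, missing if nothing reported.

    ``parent_years`` is a sequence of years (NaN allowed). Legacy cohorts
    that only recorded a category use ``ahead_category``: ``"<8"`` maps to 1
    and ``"8+"`` to missing (the category cannot resolve the 12-year cut).
    """
    if ahead_category is not None:
        if ahead_category == "<8":
            return 1.0
        if ahead_category == "8+":
            return np.nan
        raise ValueError(f"unknown parental-education category {ahead_category!r}")
    years = [y for y in parent_years if y is not None and not np.isnan(y)]
    if not years:
        return np.nan
    return 0.0 if any(y >= 12 for y in years) else 1.0


@dataclass
class AnalysisTable:
    """Model-ready table after joining and listwise deletion."""

    data: pd.DataFrame
    n: int
    manifest: dict = field(default_factory=dict)


def _column_manifest(df: pd.DataFrame) -> dict:
    codings = {
        "education": "categorical: lt_hs / hs / college (reference lt_hs)",
        "alcohol": "categorical: nondrinker / occasional / heavy (reference nondrinker)",
        "smoking": "categorical: never / former / current (reference never)",
        "female": "0/1 (reference male)",
        "high_school": "0/1: high-school degree or equivalent attained",
        "some_college": "0/1: at least some college",
        "parental_lt12": "0/1: all parents with <12 years of schooling",
        "sbp": "mmHg, harmonized (censored mean + medication constant)",
        "dbp": "mmHg, harmonized (censored mean + medication constant)",
    }
    return {
        c: {"dtype": str(df[c].dtype), "coding": codings.get(c, "numeric" if df[c].dtype.kind in "fi" else "free")}
        for c in df.columns
    }


def build_analysis_table(
    cohort: pd.DataFrame,
    harmonized_bp: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    pcs: pd.DataFrame | None = None,
    model_spec=None,
) -> AnalysisTable:
    """Join covariates, harmonized BP, risk scores and genotype PCs on
    participant id; when a :class:`~mrsbp.specs.ModelSpec` is given, apply
    listwise deletion on exactly its required columns and record the
    resulting n."""
    if "id" not in cohort.columns:
        raise SchemaError("id")
    merged = cohort.copy()
    for other in (harmonized_bp, scores, pcs):
        if other is None:
            continue
        o = other.copy()
        if "id" in o.columns:
            o = o.set_index("id")
        dup = [c for c in o.columns if c in merged.columns]
        merged = merged.join(o.drop(columns=dup), on="id", how="inner")
    if len(merged) == 0:
        raise EmptyTableError("join of cohort, blood pressure and scores is empty")

    if model_spec is not None:
        missing = [c for c in model_spec.required_columns() if c not in merged.columns]
        if missing:
            raise SchemaError(f"analysis table lacks required column(s): {', '.join(missing)}")
        if model_spec.stratum is not None:
            merged = merged[merged["ancestry"] == model_spec.stratum]
        merged = merged.dropna(subset=list(model_spec.required_columns()))
        if len(merged) == 0:
            raise EmptyTableError("no rows survive listwise deletion")
    return AnalysisTable(data=merged, n=len(merged), manifest=_column_manifest(merged))
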