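"""Blood-pressure association models and derived quantities.

The central object is :class:`BPModel`, built from a model-ready analysis
table and a :class:`~mrsbp.specs.ModelSpec`; its :meth:`~BPModel.fit`
returns a :class:`BPFitResult` carrying the coefficient table, the full
coefficient covariance, n after listwise deletion, adjusted R² and the
moments used for modifier standardization, with a ``summary()`` table,
``effect_at_level`` contrasts and ``predicted_grid`` hanging off it —
statsmodels-style.

Also here: the per-CpG effect rescaling to mmHg per 1% methylation,
Bonferroni thresholds, Cochran's Q heterogeneity test on stratified
estimates, adjusted-R² variance partitioning over the covariates-only /
+MRS / +GRS / +MRS+GRS model menu on a common sample, and survey-weighted
sensitivity fits with heteroskedasticity-robust (HC1) standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .specs import MODEL2, ModelSpec, SpecError

__all__ = [
    "BPModel",
    "BPFitResult",
    "HeterogeneityResult",
    "EffectAtLevel",
    "FitError",
    "fit_linear_model",
    "fit_interaction_model",
    "weighted_fit",
    "scale_cpg_effect",
    "bonferroni_threshold",
    "cochran_q",
    "variance_partition",
    "adjusted_r2_deltas",
    "effect_at_level",
    "predicted_grid",
]

#: Reference levels of the categorical covariates (first = reference).
CATEGORICAL_LEVELS = {
    "smoking": ("never", "former", "current"),
    "alcohol": ("nondrinker", "occasional", "heavy"),
    "education": ("lt_hs", "hs", "college"),
}


class FitError(ValueError):
    """Design-matrix or estimation failure."""


def _dummies(series: pd.Series, name: str) -> pd.DataFrame:
    levels = CATEGORICAL_LEVELS[name]
    unknown = set(series.dropna().unique()) - set(levels)
    if unknown:
        raise FitError(f"column {name!r} has unexpected level(s): {sorted(unknown)}")
    return pd.DataFrame(
        {f"{name}_{lv}": (series == lv).astype(float) for lv in levels[1:]}, index=series.index
    )


@dataclass
class EffectAtLevel:
    """Score effect at a specific modifier value: beta_main + beta_int * z."""

    level: float
    effect: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class HeterogeneityResult:
    """Cochran's Q over stratum-specific estimates."""

    strata: pd.DataFrame  # label, beta, se, weight
    pooled_beta: float
    q: float
    df: int
    p: float


def scale_cpg_effect(raw_coefficient: float) -> float:
    """Rescale a per-beta-unit CpG coefficient to mmHg per 1% methylation."""
    return raw_coefficient * 0.01


def bonferroni_threshold(m: int, alpha: float = 0.05) -> dict:
    """Bonferroni significance threshold alpha/m, reported both at full
    precision and rounded to 4 decimals."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    t = alpha / m
    return {"threshold": t, "rounded": round(t, 4), "m": m, "alpha": alpha}


def cochran_q(estimates, labels=None) -> HeterogeneityResult:
    """Inverse-variance heterogeneity test over per-stratum (beta, SE) pairs.

    Q = sum w_k (beta_k - pooled)^2 with w_k = 1/SE_k^2, compared to a
    chi-square with K-1 degrees of freedom.
    """
    est = list(estimates)
    if len(est) < 2:
        raise ValueError("need at least 2 strata")
    betas = np.array([e[0] for e in est], dtype=float)
    ses = np.array([e[1] for e in est], dtype=float)
    if (ses <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    q = float(np.sum(w * (betas - pooled) ** 2))
    df = len(est) - 1
    p = float(stats.chi2.sf(q, df))
    strata = pd.DataFrame(
        {
            "label": labels if labels is not None else [f"stratum{i}" for i in range(len(est))],
            "beta": betas,
            "se": ses,
            "weight": w,
        }
    )
    return HeterogeneityResult(strata=strata, pooled_beta=pooled, q=q, df=df, p=p)


def effect_at_level(
    beta_main: float,
    beta_interaction: float,
    z: float,
    var_main: float | None = None,
    var_interaction: float | None = None,
    cov: float | None = None,
    level: str | float | None = None,
) -> EffectAtLevel:
    """Score effect at modifier value ``z``: beta_main + beta_interaction*z,
    with the delta-method SE when the coefficient (co)variances are given.

    At the reference level (z = 0) the effect equals ``beta_main`` exactly.
    """
    if z == 0:
        eff = beta_main
    else:
        eff = beta_main + beta_interaction * z
    se = ci_low = ci_high = None
    if var_main is not None and var_interaction is not None:
        c = 0.0 if cov is None else cov
        var = var_main + z * z * var_interaction + 2.0 * z * c
        se = float(np.sqrt(max(var, 0.0)))
        ci_low, ci_high = eff - 1.959963984540054 * se, eff + 1.959963984540054 * se
    return EffectAtLevel(level=z if level is None else level, effect=eff, se=se,
                         ci_low=ci_low, ci_high=ci_high)


@dataclass
class BPFitResult:
    """Results of one blood-pressure regression.

    ``params`` holds term / beta / se / p; ``cov_params`` the full
    coefficient covariance; ``moments`` the subsample mean/SD used to
    standardize a continuous modifier (empty otherwise).
    """

    spec: ModelSpec
    params: pd.DataFrame
    cov_params: pd.DataFrame
    n: int
    df_resid: int
    rsquared: float
    rsquared_adj: float
    moments: dict = field(default_factory=dict)
    perfect_fit: bool = False
    interaction_term: str | None = None
    _design_means: pd.Series | None = None

    def beta(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "se"])

    def pvalue(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "p"])

    @property
    def primary_term(self) -> str:
        return self.spec.predictors[0]

    def effect_at_level(self, z: float, level=None) -> EffectAtLevel:
        """Effect of the primary score at modifier value ``z`` (standardized
        units for continuous modifiers, 0/1 for categorical ones)."""
        if self.interaction_term is None:
            raise FitError("model was fitted without an interaction term")
        main, inter = self.primary_term, self.interaction_term
        return effect_at_level(
            self.beta(main),
            self.beta(inter),
            z,
            var_main=float(self.cov_params.loc[main, main]),
            var_interaction=float(self.cov_params.loc[inter, inter]),
            cov=float(self.cov_params.loc[main, inter]),
            level=level,
        )

    def summary(self) -> str:
        spec = self.spec
        header = [
            f"Outcome: {spec.outcome.upper()} (mmHg)   covariates: {spec.covariate_set}"
            + (f"   stratum: {spec.stratum}" if spec.stratum else "")
            + ("   weighted (HC1 robust SE)" if spec.weight_column else ""),
            f"n = {self.n}   R2 = {self.rsquared:.4f}   adj. R2 = {self.rsquared_adj:.4f}",
        ]
        if self.moments:
            header.append(
                "modifier moments: "
                + ", ".join(f"{k}: mean={v[0]:.3f}, sd={v[1]:.3f}" for k, v in self.moments.items())
            )
        tbl = self.params.copy()
        tbl["beta"] = tbl["beta"].map(lambda v: f"{v: .4f}")
        tbl["se"] = tbl["se"].map(lambda v: f"{v:.4f}")
        tbl["p"] = tbl["p"].map(lambda v: f"{v:.3g}")
        return "\n".join(header) + "\n" + tbl.to_string(index=False)


class BPModel:
    """Linear model of harmonized blood pressure on a risk score (or CpG)
    and covariates, with optional multiplicative interaction and sampling
    weights.

    Parameters
    ----------
    table : pandas.DataFrame
        Analysis table with the columns the spec requires (harmonized
        ``sbp``/``dbp``, ``age``, ``female``, PCs, the score columns, and —
        for the fully adjusted covariate set — smoking, alcohol, BMI,
        exercise, diabetes, education and parental education).
    spec : ModelSpec
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        missing = [c for c in spec.required_columns() if c not in table.columns]
        if missing:
            raise FitError(f"table lacks required column(s): {', '.join(missing)}")
        df = table
        if spec.stratum is not None:
            df = df[df["ancestry"] == spec.stratum]
        df = df.dropna(subset=list(spec.required_columns()))
        if len(df) == 0:
            raise FitError("no rows survive listwise deletion")
        self.data = df.copy()

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, spec: ModelSpec) -> "BPModel":
        return cls(table, spec)

    # -- design ---------------------------------------------------------
    def _build_design(self):
        spec, df = self.spec, self.data
        moments: dict = {}
        cols: dict[str, pd.Series] = {}
        cols["Intercept"] = pd.Series(1.0, index=df.index)
        for p in spec.predictors:
            cols[p] = df[p].astype(float)

        age = df["age"].astype(float)
        if spec.modifier == "age":
            mean, sd = float(age.mean()), float(age.std(ddof=1))
            if sd == 0:
                raise FitError("age is constant in the analysis subsample; interaction inestimable")
            moments["age"] = (mean, sd)
            cols["age_std"] = (age - mean) / sd
        else:
            cols["age"] = age
        cols["female"] = df["female"].astype(float)
        for pc in spec.pc_columns:
            cols[pc] = df[pc].astype(float)

        if spec.covariate_set == MODEL2:
            for cat in ("smoking", "alcohol"):
                for name, col in _dummies(df[cat], cat).items():
                    cols[name] = col
            for num in ("bmi", "exercise", "diabetes"):
                cols[num] = df[num].astype(float)
            if spec.modifier is not None:
                cols["high_school"] = df["high_school"].astype(float)
                cols["some_college"] = df["some_college"].astype(float)
            else:
                for name, col in _dummies(df["education"], "education").items():
                    cols[name] = col
            cols["parental_lt12"] = df["parental_lt12"].astype(float)

        interaction_term = None
        if spec.modifier is not None:
            mod_col = spec.modifier_column
            if spec.modifier == "age":
                mod = cols["age_std"]
                mod_name = "age_std"
            elif spec.modifier == "grs":
                raw = df[mod_col].astype(float)
                mean, sd = float(raw.mean()), float(raw.std(ddof=1))
                if sd == 0:
                    raise FitError("GRS is constant in the analysis subsample; interaction inestimable")
                moments[mod_col] = (mean, sd)
                mod_name = f"{mod_col}_std"
                mod = (raw - mean) / sd
                cols[mod_name] = mod
            else:
                mod = df[mod_col].astype(float)
                if mod.nunique() < 2:
                    raise FitError(f"modifier {mod_col!r} is constant; interaction inestimable")
                mod_name = mod_col
                if mod_name not in cols:
                    cols[mod_name] = mod
            primary = spec.predictors[0]
            interaction_term = f"{primary}_x_{mod_name}"
            cols[interaction_term] = cols[primary] * mod

        X = pd.DataFrame(cols)
        y = df[spec.outcome].astype(float)
        return y, X, moments, interaction_term

    # -- estimation -----------------------------------------------------
    def fit(self) -> BPFitResult:
        spec = self.spec
        y, X, moments, interaction_term = self._build_design()
        n, p = X.shape
        if n < p + 2:
            raise FitError(f"n = {n} is too small for {p} parameters")
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < p:
            # pivoted QR: columns beyond the numerical rank are the culprits
            from scipy.linalg import qr as _qr

            _, _, piv = _qr(X.to_numpy(), pivoting=True, mode="economic")
            bad = [X.columns[j] for j in piv[rank:]]
            raise FitError(f"design matrix is rank deficient; collinear column(s): {bad}")

        if spec.weight_column is not None:
            w = self.data[spec.weight_column].astype(float)
            if (w <= 0).any():
                raise FitError("sampling weights must be positive")
            res = sm.WLS(y, X, weights=w).fit(cov_type="HC1")
        else:
            res = sm.OLS(y, X).fit()

        perfect = bool(res.ssr <= 1e-12 * max(1.0, float((y**2).sum())))
        params = pd.DataFrame(
            {"term": X.columns, "beta": res.params.to_numpy(), "se": res.bse.to_numpy(),
             "p": res.pvalues.to_numpy()}
        )
        return BPFitResult(
            spec=spec,
            params=params,
            cov_params=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
            n=n,
            df_resid=int(res.df_resid),
            rsquared=float(res.rsquared),
            rsquared_adj=float(res.rsquared_adj),
            moments=moments,
            perfect_fit=perfect,
            interaction_term=interaction_term,
            _design_means=X.mean(),
        )


# -- functional conveniences over BPModel -------------------------------

def fit_linear_model(table: pd.DataFrame, spec: ModelSpec) -> BPFitResult:
    """Ordinary least squares for the given spec (listwise deletion applied)."""
    return BPModel(table, spec).fit()


def fit_interaction_model(table: pd.DataFrame, spec: ModelSpec) -> BPFitResult:
    """Fit a model with a score-by-modifier multiplicative term."""
    if spec.modifier is None:
        raise SpecError("spec has no modifier")
    return BPModel(table, spec).fit()


def weighted_fit(table: pd.DataFrame, spec: ModelSpec) -> BPFitResult:
    """Weighted least squares with HC1 robust standard errors."""
    if spec.weight_column is None:
        raise SpecError("spec has no weight column")
    return BPModel(table, spec).fit()


def adjusted_r2_deltas(menu: dict) -> dict:
    """Pairwise differences of an adjusted-R² menu (given on the percent
    scale, as reported): ``menu`` maps model label -> adjusted R²."""
    labels = list(menu)
    return {
        f"{a} - {b}": menu[a] - menu[b] for i, a in enumerate(labels) for b in labels[:i]
    }


def variance_partition(
    table: pd.DataFrame,
    spec: ModelSpec,
    mrs_column: str | None = None,
    grs_column: str | None = None,
) -> pd.DataFrame:
    """Adjusted-R² menu over covariates-only / +MRS / +GRS / +MRS+GRS.

    All four models are fitted on the single common listwise-deleted sample
    (rows complete for the covariates and both scores), so the reported n is
    identical across the menu. Returns a frame with adjusted R² as a
    fraction, as a percent rounded to 1 decimal, and the delta versus the
    covariates-only model.
    """
    mrs_column = mrs_column or f"mrs_{spec.outcome}"
    grs_column = grs_column or f"grs_{spec.outcome}"
    menu = {
        "covariates": (),
        "covariates+mrs": (mrs_column,),
        "covariates+grs": (grs_column,),
        "covariates+mrs+grs": (mrs_column, grs_column),
    }
    base = ModelSpec(
        outcome=spec.outcome,
        predictors=(mrs_column, grs_column),
        covariate_set=spec.covariate_set,
        stratum=spec.stratum,
        weight_column=spec.weight_column,
        n_pcs=spec.n_pcs,
    )
    common = table
    if base.stratum is not None:
        common = common[common["ancestry"] == base.stratum]
    common = common.dropna(subset=list(base.required_columns()))
    rows = []
    for label, preds in menu.items():
        s = ModelSpec(
            outcome=spec.outcome,
            predictors=preds,
            covariate_set=spec.covariate_set,
            stratum=None,  # already restricted
            weight_column=spec.weight_column,
            n_pcs=spec.n_pcs,
        )
        fit = BPModel(common, s).fit()
        rows.append(
            {"model": label, "n": fit.n, "adj_r2": fit.rsquared_adj,
             "adj_r2_pct": round(100 * fit.rsquared_adj, 1)}
        )
    out = pd.DataFrame(rows)
    out["delta_vs_covariates_pct"] = (out["adj_r2_pct"] - out.loc[0, "adj_r2_pct"]).round(1)
    return out


def predicted_grid(
    fit: BPFitResult,
    modifier_levels,
    score_range=(-2.0, 2.0),
    n_points: int = 21,
) -> pd.DataFrame:
    """Predicted outcome over a score grid at given modifier levels, with all
    other covariates held at their analysis-subsample means.

    ``modifier_levels`` are on the same scale as the fitted interaction
    (standardized units for continuous modifiers — e.g. the 25th/75th
    percentile values after standardization — and 0/1 for categorical ones).
    """
    if fit.interaction_term is None:
        raise FitError("model was fitted without an interaction term")
    means = fit._design_means.copy()
    primary = fit.primary_term
    mod_name = fit.interaction_term[len(primary) + 3 :]
    betas = fit.params.set_index("term")["beta"]
    base_cols = means.copy()
    base_cols[primary] = 0.0
    base_cols[mod_name] = 0.0
    base_cols[fit.interaction_term] = 0.0
    base = float(base_cols @ betas)

    scores = np.linspace(score_range[0], score_range[1], n_points)
    rows = []
    for z in modifier_levels:
        for s in scores:
            pred = (
                base
                + betas[primary] * s
                + betas[mod_name] * z
                + betas[fit.interaction_term] * s * z
            )
            rows.append({"modifier_level": z, "score": s, "predicted": float(pred)})
    return pd.DataFrame(rows)
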