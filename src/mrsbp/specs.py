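"""Model specifications shared by the phenotyping and association stages."""

from __future__ import annotations

from dataclasses import dataclass, field


#: Covariates of the minimally adjusted model: age, sex, 10 genotype PCs.
MODEL1 = "model1"
#: Model 1 covariates plus behavioral/socioeconomic risk factors.
MODEL2 = "model2"

VALID_OUTCOMES = ("sbp", "dbp")
VALID_COVARIATE_SETS = (MODEL1, MODEL2)
#: Effect modifiers allowed in interaction models. ``grs`` and ``age`` are
#: continuous (standardized on the analysis subsample); the rest are 0/1.
VALID_MODIFIERS = ("grs", "age", "female", "high_school", "some_college")

MODEL2_EXTRA_COLUMNS = (
    "smoking",
    "alcohol",
    "bmi",
    "exercise",
    "diabetes",
    "education",
    "parental_lt12",
)


class SpecError(ValueError):
    """Invalid model specification."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one blood-pressure regression.

    Parameters
    ----------
    outcome : {"sbp", "dbp"}
        Harmonized blood-pressure outcome, mmHg.
    predictors : tuple of str
        Primary predictor column(s): a CpG residual column, ``mrs_sbp``/
        ``mrs_dbp``, ``grs_sbp``/``grs_dbp``, or an MRS+GRS pair.
    covariate_set : {"model1", "model2"}
        ``model1`` adjusts for age, sex and the genotype PCs; ``model2``
        additionally adjusts for smoking, alcohol, BMI, exercise, diabetes,
        educational attainment and parental education.
    modifier : str, optional
        Effect modifier for a multiplicative interaction with the first
        predictor (which must then be an MRS). Continuous modifiers are
        standardized using the analysis subsample's moments. When a modifier
        is present, educational attainment enters as the two
        high-school/some-college dummies rather than the 3-level factor.
    stratum : str, optional
        Ancestry label to restrict the analysis to (``None`` = full sample).
    weight_column : str, optional
        Sampling-weight column for weighted least squares with
        heteroskedasticity-robust standard errors.
    n_pcs : int
        Number of genotype principal components adjusted for.
    """

    outcome: str
    predictors: tuple = ()
    covariate_set: str = MODEL1
    modifier: str | None = None
    stratum: str | None = None
    weight_column: str | None = None
    n_pcs: int = 10

    def __post_init__(self):
        if self.outcome not in VALID_OUTCOMES:
            raise SpecError(f"outcome must be one of {VALID_OUTCOMES}, got {self.outcome!r}")
        if self.covariate_set not in VALID_COVARIATE_SETS:
            raise SpecError(
                f"covariate_set must be one of {VALID_COVARIATE_SETS}, got {self.covariate_set!r}"
            )
        if isinstance(self.predictors, str):
            object.__setattr__(self, "predictors", (self.predictors,))
        else:
            object.__setattr__(self, "predictors", tuple(self.predictors))
        if self.modifier is not None:
            if self.modifier not in VALID_MODIFIERS:
                raise SpecError(f"modifier must be one of {VALID_MODIFIERS}, got {self.modifier!r}")
            if not self.predictors or not self.predictors[0].startswith("mrs"):
                raise SpecError("interaction models require an MRS as the primary predictor")
        if self.n_pcs < 0:
            raise SpecError("n_pcs must be non-negative")

    @property
    def pc_columns(self) -> tuple:
        return tuple(f"pc{i}" for i in range(1, self.n_pcs + 1))

    @property
    def modifier_column(self) -> str | None:
        """Column holding the raw modifier (``grs`` maps to the outcome's GRS)."""
        if self.modifier is None:
            return None
        if self.modifier == "grs":
            return f"grs_{self.outcome}"
        return self.modifier

    def required_columns(self) -> tuple:
        """Columns whose missingness triggers listwise deletion for this fit."""
        cols = [self.outcome, *self.predictors, "age", "female", *self.pc_columns]
        if self.covariate_set == MODEL2:
            if self.modifier is not None:
                # interaction analyses use the two education dummies
                extras = [c for c in MODEL2_EXTRA_COLUMNS if c != "education"]
                extras += ["high_school", "some_college"]
            else:
                extras = list(MODEL2_EXTRA_COLUMNS)
            cols += extras
        if self.modifier is not None and self.modifier_column not in cols:
            cols.append(self.modifier_column)
        if self.stratum is not None:
            cols.append("ancestry")
        if self.weight_column is not None:
            cols.append(self.weight_column)
        # preserve order, drop duplicates
        seen, out = set(), []
        for c in cols:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return tuple(out)
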