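"""Removal of cell-composition and chip/slide batch structure from beta values.

Each CpG's beta values are modelled by restricted maximum likelihood as

    beta ~ intercept + cell fractions (fixed) + chip (random intercept)
           + slide (random intercept, nested within chip)

and the *conditional* residuals — observed value minus the fixed-effect fit
minus the predicted (BLUP) chip and slide intercepts — are returned, centered
to mean zero. Subtracting the predicted random intercepts is deliberate: the
point of the adjustment is to strip chip/slide variance from the values that
enter the risk scores, not merely to estimate it.

One cell-fraction column is dropped before fitting (the fractions are
compositional and sum to one, so the full set is collinear with the
intercept); the dropped column is recorded in the fit diagnostics.

A convergence fallback ladder handles degenerate inputs: (1) drop the slide
random effect, (2) drop the chip random effect, (3) plain OLS on the cell
fractions. Each CpG's path through the ladder is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "MethylationMatrix",
    "AdjustedMethylation",
    "AdjustmentError",
    "fit_adjustment_model",
    "adjust_matrix",
]


class AdjustmentError(RuntimeError):
    """A CpG's adjustment model failed on every rung of the fallback ladder."""


@dataclass
class MethylationMatrix:
    """Beta values with batch annotations and estimated cell fractions.

    All four members are indexed by sample id in identical order.
    """

    betas: pd.DataFrame  # samples x CpGs, values in [0, 1]
    chip: pd.Series
    slide: pd.Series
    cell_fractions: pd.DataFrame  # samples x cell types, rows sum to 1

    def validate(self, atol_fraction_sum: float = 1e-6) -> None:
        b = self.betas.to_numpy()
        if np.nanmin(b) < 0 or np.nanmax(b) > 1:
            raise ValueError("beta values must lie in [0, 1]")
        if not (self.betas.index.equals(self.chip.index) and
                self.betas.index.equals(self.slide.index) and
                self.betas.index.equals(self.cell_fractions.index)):
            raise ValueError("betas, chip, slide and cell fractions must share a sample index")
        if self.chip.isna().any() or self.slide.isna().any():
            raise ValueError("every sample needs a chip and a slide id")
        f = self.cell_fractions.to_numpy()
        if (f < 0).any():
            raise ValueError("cell fractions must be non-negative")
        if np.abs(f.sum(axis=1) - 1.0).max() > atol_fraction_sum:
            raise ValueError("cell-fraction rows must sum to 1 within tolerance")
        # slide ids must be globally unique: a slide may not span chips
        span = pd.DataFrame({"chip": self.chip, "slide": self.slide}).groupby("slide")["chip"].nunique()
        if (span > 1).any():
            bad = span[span > 1].index.tolist()
            raise ValueError(f"slide id(s) appear under multiple chips: {bad}")


@dataclass
class AdjustedMethylation:
    """Conditional residuals plus per-CpG variance components."""

    adjusted: pd.DataFrame  # samples x CpGs, mean-zero residuals
    variance_components: pd.DataFrame  # index CpG: chip_sd, slide_sd, residual_sd, path
    dropped_cell_column: str | None = None
    diagnostics: dict = field(default_factory=dict)


def _ols_residuals(y: np.ndarray, X: np.ndarray):
    res = sm.OLS(y, X).fit()
    return res.resid, float(res.resid.std(ddof=X.shape[1]))


def fit_adjustment_model(
    cpg_values: pd.Series,
    cell_fractions: pd.DataFrame,
    chip: pd.Series,
    slide: pd.Series,
    drop_cell_column: str | None = None,
):
    """Fit one CpG's adjustment model and return
    ``(residuals, variance_components, path)``.

    ``variance_components`` is a dict with ``chip_sd``, ``slide_sd`` and
    ``residual_sd``; ``path`` names the rung of the fallback ladder used
    (``mixed``, ``mixed_no_slide``, ``mixed_no_chip``, ``ols``,
    ``constant``).
    """
    y = cpg_values.to_numpy(dtype=float)
    n = len(y)
    if np.ptp(y) == 0.0:
        zeros = pd.Series(np.zeros(n), index=cpg_values.index)
        return zeros, {"chip_sd": 0.0, "slide_sd": 0.0, "residual_sd": 0.0}, "constant"

    if drop_cell_column is None:
        drop_cell_column = cell_fractions.columns[-1]
    F = cell_fractions.drop(columns=[drop_cell_column]).to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), F])

    chip_codes = pd.Categorical(chip)
    slide_codes = pd.Categorical(slide)
    chip_sizes = pd.Series(chip.to_numpy()).value_counts()
    slide_sizes = pd.Series(slide.to_numpy()).value_counts()
    chip_ok = len(chip_codes.categories) >= 2 and (chip_sizes >= 2).sum() >= 2
    slide_ok = (
        len(slide_codes.categories) >= 2
        and (slide_sizes >= 2).sum() >= 2
        and len(slide_codes.categories) > len(chip_codes.categories)
    )

    errors = []
    data = pd.DataFrame(F, columns=[f"f{i}" for i in range(F.shape[1])])
    data["y"] = y
    data["chip"] = chip_codes.codes.astype(str)
    data["slide"] = slide_codes.codes.astype(str)
    fixed = "y ~ " + (" + ".join(data.columns[: F.shape[1]]) if F.shape[1] else "1")

    attempts = []
    if chip_ok and slide_ok:
        attempts.append("mixed")
    if chip_ok:
        attempts.append("mixed_no_slide")
    if slide_ok and not chip_ok:
        attempts.append("mixed_no_chip")
    attempts.append("ols")

    for path in attempts:
        try:
            if path == "ols":
                resid, rsd = _ols_residuals(y, X)
                resid = resid - resid.mean()
                return (
                    pd.Series(resid, index=cpg_values.index),
                    {"chip_sd": 0.0, "slide_sd": 0.0, "residual_sd": rsd},
                    path,
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                if path == "mixed":
                    model = MixedLM.from_formula(
                        fixed, data, groups="chip", re_formula="1",
                        vc_formula={"slide": "0 + C(slide)"},
                    )
                elif path == "mixed_no_slide":
                    model = MixedLM.from_formula(fixed, data, groups="chip", re_formula="1")
                else:  # mixed_no_chip
                    model = MixedLM.from_formula(fixed, data, groups="slide", re_formula="1")
                result = model.fit(reml=True)
            if not result.converged:
                errors.append(f"{path}: did not converge")
                continue
            chip_var = float(result.cov_re.iloc[0, 0])
            slide_var = float(result.vcomp[0]) if path == "mixed" else 0.0
            if path == "mixed_no_chip":
                slide_var, chip_var = chip_var, 0.0
            resid_var = float(result.scale)

            # conditional residuals: subtract fixed fit and predicted
            # random intercepts
            fitted_fixed = np.asarray(result.predict(data))
            blup = np.zeros(n)
            group_col = "slide" if path == "mixed_no_chip" else "chip"
            re = result.random_effects
            groups = data[group_col].to_numpy()
            for g, eff in re.items():
                in_g = groups == str(g)
                vals = eff.to_numpy()
                names = list(eff.index)
                blup[in_g] += vals[0]  # group intercept
                if path == "mixed" and len(vals) > 1:
                    # remaining entries are slide dummies within this chip
                    for name, v in zip(names[1:], vals[1:]):
                        # vc names look like "slide[C(slide)[3]]"
                        stripped = name.rstrip("]")
                        sid = stripped[stripped.rindex("[") + 1 :]
                        if sid.startswith("T."):
                            sid = sid[2:]
                        matched = in_g & (data["slide"] == sid).to_numpy()
                        if not matched.any():
                            raise AdjustmentError(
                                f"could not map random-effect name {name!r} to a slide"
                            )
                        blup[matched] += v
            resid = y - fitted_fixed - blup
            resid = resid - resid.mean()
            return (
                pd.Series(resid, index=cpg_values.index),
                {
                    "chip_sd": float(np.sqrt(max(chip_var, 0.0))),
                    "slide_sd": float(np.sqrt(max(slide_var, 0.0))),
                    "residual_sd": float(np.sqrt(max(resid_var, 0.0))),
                },
                path,
            )
        except Exception as exc:  # noqa: BLE001 - ladder records and moves on
            errors.append(f"{path}: {exc}")
            continue
    raise AdjustmentError(
        f"adjustment failed for CpG {cpg_values.name!r}: " + "; ".join(errors)
    )


def adjust_matrix(m: MethylationMatrix, drop_cell_column: str | None = None) -> AdjustedMethylation:
    """Apply :func:`fit_adjustment_model` independently to every CpG,
    preserving sample order."""
    m.validate()
    dropped = drop_cell_column or m.cell_fractions.columns[-1]
    residuals = {}
    rows = []
    failures = []
    for cpg in m.betas.columns:
        try:
            resid, vc, path = fit_adjustment_model(
                m.betas[cpg], m.cell_fractions, m.chip, m.slide, drop_cell_column=dropped
            )
        except AdjustmentError as exc:
            failures.append(str(exc))
            continue
        residuals[cpg] = resid
        rows.append({"cpg": cpg, **vc, "path": path})
    if failures:
        raise AdjustmentError("; ".join(failures))
    adjusted = pd.DataFrame(residuals, index=m.betas.index)[list(m.betas.columns)]
    vcs = pd.DataFrame(rows).set_index("cpg")
    return AdjustedMethylation(
        adjusted=adjusted,
        variance_components=vcs,
        dropped_cell_column=dropped,
        diagnostics={"n_samples": len(m.betas), "paths": vcs["path"].value_counts().to_dict()},
    )
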