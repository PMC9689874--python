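"""Stable file contracts: one TSV dialect, provenance headers, validation.

All tabular files are tab-separated with a header row, UTF-8, '.' decimal
and ``NA`` for missing. Writers prepend provenance comment lines
(``# stage: ...``, ``# seed: ...``, ``# config_hash: ...``); readers skip
``#`` lines, so every writer's output round-trips through its paired reader
at full float precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_tsv",
    "read_tsv",
    "config_hash",
    "ValidationReport",
    "validate_inputs",
]

NA_TOKEN = "NA"


def config_hash(config: dict) -> str:
    """Short hash of the semantically meaningful configuration fields.

    Canonical JSON (sorted keys) so the hash changes iff a field's value
    changes.
    """
    def conv(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, (tuple, list, np.ndarray)):
            return [conv(x) for x in v]
        if isinstance(v, dict):
            return {k: conv(x) for k, x in sorted(v.items())}
        if isinstance(v, Path):
            return str(v)
        return v

    payload = json.dumps(conv(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_tsv(df: pd.DataFrame, path, stage: str = "", seed=None, cfg_hash: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if stage:
            fh.write(f"# stage: {stage}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if cfg_hash:
            fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.17g")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=[NA_TOKEN],
        float_precision="round_trip", **kwargs,
    )


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = [f"ERROR: {e}" for e in self.errors] + [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "clean"


def validate_inputs(paths: dict, fraction_sum_tol: float = 0.05) -> ValidationReport:
    """Check the standard input files named in ``paths`` (any subset of
    ``methylation``, ``cell_fractions``, ``batches``, ``genotypes``,
    ``cohort``, ``weights_cpg``, ``weights_snp``).

    Beta range and dosage range violations, duplicate ids and duplicate
    weight rows are errors; cell-fraction rows off unity by more than
    ``fraction_sum_tol`` are errors, smaller deviations warnings.
    """
    rep = ValidationReport()

    def load(key):
        p = paths.get(key)
        if p is None:
            return None
        p = Path(p)
        if not p.exists():
            rep.errors.append(f"{key}: file not found: {p}")
            return None
        try:
            return read_tsv(p)
        except Exception as exc:  # noqa: BLE001
            rep.errors.append(f"{key}: unreadable ({exc})")
            return None

    meth = load("methylation")
    if meth is not None:
        vals = meth.drop(columns=["id"], errors="ignore").select_dtypes("number")
        if ((vals < 0) | (vals > 1)).any().any():
            rep.errors.append("methylation: beta values outside [0, 1]")
        if "id" in meth.columns and meth["id"].duplicated().any():
            rep.errors.append("methylation: duplicate sample ids")

    cf = load("cell_fractions")
    if cf is not None:
        vals = cf.drop(columns=["id"], errors="ignore").select_dtypes("number")
        sums = vals.sum(axis=1)
        off = (sums - 1.0).abs()
        if (off > fraction_sum_tol).any():
            rep.errors.append(
                f"cell_fractions: row sums deviate from 1 by more than {fraction_sum_tol}"
            )
        elif (off > 1e-6).any():
            rep.warnings.append(
                f"cell_fractions: row sums off unity by up to {off.max():.2e} "
                f"(tolerance {fraction_sum_tol})"
            )
        if (vals < 0).any().any():
            rep.errors.append("cell_fractions: negative fractions")

    geno = load("genotypes")
    if geno is not None:
        vals = geno.drop(columns=["id"], errors="ignore").select_dtypes("number")
        if ((vals < 0) | (vals > 2)).any().any():
            rep.errors.append("genotypes: dosages outside [0, 2]")

    cohort = load("cohort")
    if cohort is not None and "id" in cohort.columns and cohort["id"].duplicated().any():
        rep.errors.append("cohort: duplicate participant ids")

    for key in ("weights_cpg", "weights_snp"):
        wt = load(key)
        if wt is None:
            continue
        need = {"feature_id", "trait", "weight"}
        if not need.issubset(wt.columns):
            rep.errors.append(f"{key}: missing column(s) {sorted(need - set(wt.columns))}")
            continue
        if wt.duplicated(subset=["feature_id", "trait"]).any():
            rep.errors.append(f"{key}: duplicate (feature, trait) rows")
        if not np.isfinite(wt["weight"]).all():
            rep.errors.append(f"{key}: non-finite weights")
        if meth is not None and key == "weights_cpg":
            cpg_cols = [c for c in meth.columns if c != "id"]
            absent = sorted(set(wt["feature_id"]) - set(cpg_cols))
            if absent:
                rep.errors.append(f"{key}: weighted CpG(s) absent from methylation matrix: {absent[:5]}")
    return rep
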