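"""Cohort CSV reading/writing and the JSON validation report.

The single interchange format for cohorts is a flat CSV, one row per
child, with a fixed column set (11 item columns, demographics, the
gold-standard label); booleans are encoded 0/1.  Reports are JSON with
both full-precision proportions and display-rounded percentages.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import diagnostics
from .instrument import ITEM_COLUMNS, MAX_ITEM_VALUE
from .prevalence import subgroup_prevalence
from .reconstruction import round_half_up

SCHEMA_COLUMNS: tuple[str, ...] = (
    "record_id", "age_years", "sex", "province", "residence", "education",
    "parents_alive", "caregiver", "discloser", "art_months_band",
    "viral_suppressed", *ITEM_COLUMNS, "gold_standard_depressed",
)

CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "province": ("East", "West", "Kigali", "North", "South"),
    "residence": ("urban", "rural"),
    "education": ("primary", "secondary"),
    "parents_alive": ("both", "one"),
    "caregiver": ("parents", "other"),
    "discloser": ("parents", "parent_with_provider", "provider"),
    "art_months_band": ("<24", "25-60", "61-120", "121+"),
}

_BOOL_COLUMNS = ("viral_suppressed", "gold_standard_depressed")


class CohortValidationError(ValueError):
    """Raised when a cohort CSV violates the schema; the message names the
    offending row (1-based data row) and column."""


def _fail(row: Optional[int], column: str, message: str) -> None:
    where = f"column '{column}'" if row is None else \
        f"row {row}, column '{column}'"
    raise CohortValidationError(f"{where}: {message}")


def validate_cohort(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a cohort DataFrame against the schema.

    Returns a typed copy (integer items/ages, boolean flags).  Extra
    columns (e.g. ``facility_id``) are carried through untouched.
    """
    if len(frame) == 0:
        raise CohortValidationError("empty cohort")
    for col in SCHEMA_COLUMNS:
        if col not in frame.columns:
            _fail(None, col, "missing column")
    out = frame.copy()
    int_cols = ("age_years", *ITEM_COLUMNS)
    for col in int_cols:
        numeric = pd.to_numeric(out[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            _fail(int(np.flatnonzero(bad)[0]) + 1, col, "non-integer value")
        out[col] = numeric.astype(int)
    for col in ITEM_COLUMNS:
        bad = (out[col] < 0) | (out[col] > MAX_ITEM_VALUE)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            _fail(row + 1, col,
                  f"item value {out[col].iloc[row]} outside 0-{MAX_ITEM_VALUE}")
    bad = (out["age_years"] < 7) | (out["age_years"] > 14)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        _fail(row + 1, "age_years",
              f"age {out['age_years'].iloc[row]} outside 7-14")
    for col, levels in CATEGORY_LEVELS.items():
        values = out[col].astype(str)
        bad = ~values.isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            _fail(row + 1, col,
                  f"unknown category {values.iloc[row]!r} "
                  f"(expected one of {', '.join(levels)})")
        out[col] = values
    for col in _BOOL_COLUMNS:
        numeric = pd.to_numeric(out[col], errors="coerce")
        bad = ~numeric.isin([0, 1])
        if bad.any():
            _fail(int(np.flatnonzero(bad)[0]) + 1, col,
                  "boolean column must be encoded 0/1")
        out[col] = numeric.astype(bool)
    if out["record_id"].duplicated().any():
        row = int(np.flatnonzero(out["record_id"].duplicated())[0])
        _fail(row + 1, "record_id", "duplicate identifier")
    return out


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"record_id": str})
    except pd.errors.EmptyDataError:
        raise CohortValidationError("empty cohort") from None
    return validate_cohort(frame)


def write_cohort(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort CSV with 0/1-encoded booleans and LF line endings
    (so identical frames produce byte-identical files)."""
    out = frame.copy()
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(bool).astype(int)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, lineterminator="\n")


def with_age_band(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with an ``age_band`` column (7-9 / 10-12 / 13-14)
    derived from ``age_years``, for banded subgroup analyses."""
    out = records.copy()
    age = out["age_years"].astype(int)
    out["age_band"] = np.select(
        [age <= 9, age <= 12], ["7-9", "10-12"], default="13-14")
    return out


def _pct(x: Optional[float]) -> Optional[float]:
    return None if x is None else 100.0 * x


def _display(x: Optional[float], decimals: int = 1) -> Optional[float]:
    return None if x is None else round_half_up(x, decimals)


def build_validation_report(records: pd.DataFrame, cutoff_min: int = 4,
                            cutoff_max: int = 10,
                            by: Optional[list[str]] = None,
                            conf_level: float = 0.95, deff: float = 1.0,
                            ci_method: str = "wilson") -> dict:
    """Assemble the JSON validation report for a cohort.

    Contains the cohort composition, one block per cutoff (counts and
    operating characteristics, raw and display-rounded), the empirical
    ROC AUC, the balanced-accuracy-optimal cutoff, and optional subgroup
    prevalence blocks.
    """
    labels = records["gold_standard_depressed"].astype(bool)
    table = diagnostics.operating_table(records, cutoff_min, cutoff_max)
    roc = diagnostics.roc_curve(records)
    rows = []
    for cutoff, s in table:
        cm = s.counts
        rows.append({
            "cutoff": cutoff,
            "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
            "sensitivity": s.sensitivity,
            "specificity": s.specificity,
            "ppv": s.ppv,
            "npv": s.npv,
            "balanced_accuracy": s.balanced_accuracy,
            "display": {
                "sensitivity_pct": _display(_pct(s.sensitivity)),
                "specificity_pct": _display(_pct(s.specificity)),
                "ppv_pct": _display(_pct(s.ppv)),
                "npv_pct": _display(_pct(s.npv)),
                "balanced_accuracy": _display(s.balanced_accuracy, 3),
            },
        })
    report = {
        "n": int(len(records)),
        "n_pos": int(labels.sum()),
        "n_neg": int((~labels).sum()),
        "rows": rows,
        "empirical_auc": roc.auc,
        "optimal_cutoff": diagnostics.optimal_cutoff(table),
    }
    if by:
        report["subgroups"] = {}
        for var in by:
            source = records
            if var == "age_band" and "age_band" not in records.columns:
                source = with_age_band(records)
            sub = subgroup_prevalence(source, var, method=ci_method,
                                      conf_level=conf_level, deff=deff)
            report["subgroups"][var] = [
                {"level": str(r.level), "k": int(r.k), "n": int(r.n),
                 "proportion": float(r.proportion),
                 "prevalence_pct_display": _display(100.0 * r.proportion),
                 "ci_low": float(r.ci_low), "ci_high": float(r.ci_high)}
                for r in sub.itertuples()
            ]
    return report


def write_json(obj: dict, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
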