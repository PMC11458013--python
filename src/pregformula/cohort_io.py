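"""Cohort data model, CSV input/output and record validation.

The unit of analysis is a mother observed over her first two successive
singleton pregnancies, together with her second child's measured BMI at
age 4-5 years.  The on-disk format is a wide CSV with one row per mother;
the column dictionary is :data:`COLUMN_SPEC`.

Only systolic blood pressure (``p1_sbp``/``p2_sbp``) and caesarean delivery
(``b1_caesarean``/``b2_caesarean``) may be missing (empty cells); every
other column is mandatory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field


import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

ETHNICITIES = (
    "White",
    "Mixed",
    "Asian",
    "Black/African/Caribbean",
    "Chinese",
    "Other",
    "NotStated",
)
EDUCATIONS = ("University+", "College", "Secondary-")
BMI_CATEGORIES = ("healthy", "overweight", "obese")
SEXES = ("M", "F")

#: column name -> (kind, allow_missing). Kinds: id, float, int, cat:<group>
COLUMN_SPEC: dict[str, tuple[str, bool]] = {
    "id": ("id", False),
    "age_p1": ("float", False),
    "ethnicity": ("cat:ethnicity", False),
    "education": ("cat:education", False),
    "employed": ("int", False),
    "interpregnancy_interval_months": ("float", False),
    "p1_gestation_at_ana_days": ("float", False),
    "p1_weight_kg": ("float", False),
    "p1_height_m": ("float", False),
    "p1_bmi": ("float", False),
    "p1_bmi_category": ("cat:bmi", False),
    "p1_smoking": ("int", False),
    "p1_sbp": ("float", True),
    "p1_art": ("int", False),
    "p2_gestation_at_ana_days": ("float", False),
    "p2_weight_kg": ("float", False),
    "p2_height_m": ("float", False),
    "p2_bmi": ("float", False),
    "p2_bmi_category": ("cat:bmi", False),
    "p2_smoking": ("int", False),
    "p2_sbp": ("float", True),
    "p2_art": ("int", False),
    "b1_birthweight_g": ("float", False),
    "b1_gestational_age_days": ("float", False),
    "b1_caesarean": ("int", True),
    "b2_birthweight_g": ("float", False),
    "b2_gestational_age_days": ("float", False),
    "b2_caesarean": ("int", True),
    "c2_sex": ("cat:sex", False),
    "c2_age_years": ("float", False),
    "c2_bmi": ("float", False),
    "c2_zscore": ("float", False),
    "c2_overweight_obesity": ("int", False),
    "c2_obesity": ("int", False),
}

_CAT_LEVELS = {
    "ethnicity": ETHNICITIES,
    "education": EDUCATIONS,
    "bmi": BMI_CATEGORIES,
    "sex": SEXES,
}

COLUMNS = tuple(COLUMN_SPEC)


class SchemaError(ValueError):
    """The CSV header or column types do not match the cohort schema."""


class RowParseError(ValueError):
    """A cell could not be parsed; carries the row id and field name."""

    def __init__(self, row_id: str, field_name: str, message: str):
        self.row_id = row_id
        self.field_name = field_name
        super().__init__(f"row {row_id!r}, field {field_name!r}: {message}")


@dataclass
class CohortTable:
    """An ordered collection of mother records backed by a DataFrame."""

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if tuple(self.df.columns) != COLUMNS:
            missing = [c for c in COLUMNS if c not in self.df.columns]
            if missing:
                raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
            self.df = self.df.loc[:, list(COLUMNS)]
        if not self.df.index.equals(pd.RangeIndex(len(self.df))):
            self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), self.provenance)

    def content_hash(self) -> str:
        payload = self.df.to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class Violation:
    row_id: str | None
    field: str | None
    message: str

    def to_dict(self) -> dict:
        return {"row_id": self.row_id, "field": self.field, "message": self.message}


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def to_json(self) -> str:
        return json.dumps([v.to_dict() for v in self.violations], indent=2)


def _convert_column(raw: pd.Series, name: str, ids: pd.Series) -> pd.Series:
    kind, allow_missing = COLUMN_SPEC[name]
    blank = raw.isna() | (raw.astype(str).str.strip() == "")
    if blank.any() and not allow_missing and kind != "id":
        bad = ids[blank].iloc[0]
        raise RowParseError(str(bad), name, "mandatory value is missing")
    if kind == "id":
        return raw.astype(str)
    if kind.startswith("cat:"):
        levels = _CAT_LEVELS[kind.split(":", 1)[1]]
        vals = raw.astype(str).str.strip()
        bad = ~vals.isin(levels) & ~blank
        if bad.any():
            i = bad.idxmax()
            raise RowParseError(str(ids.loc[i]), name, f"value {vals.loc[i]!r} not in {levels}")
        return vals.where(~blank, other=np.nan)
    numeric = pd.to_numeric(raw.where(~blank, other=np.nan), errors="coerce")
    failed = numeric.isna() & ~blank
    if failed.any():
        i = failed.idxmax()
        raise RowParseError(str(ids.loc[i]), name, f"cannot parse {raw.loc[i]!r} as a number")
    if kind == "int" and not allow_missing:
        return numeric.astype(np.int64)
    return numeric.astype(float)


def read_cohort(path, schema_version: str = SCHEMA_VERSION) -> CohortTable:
    """Read and type-check a cohort CSV.

    Raises :class:`SchemaError` if a mandatory column is absent and
    :class:`RowParseError` (with row id and field) on an unparseable cell.
    Missing sbp/caesarean cells are kept as explicit NaN, never imputed.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    ids = raw["id"].astype(str)
    data = {name: _convert_column(raw[name], name, ids) for name in COLUMNS}
    return CohortTable(pd.DataFrame(data), provenance=f"read from {path}")


def write_cohort(table: CohortTable, path) -> None:
    """Write the cohort to CSV; missing values become empty cells."""
    df = table.df.copy()
    # render optionally-missing int-like columns without trailing ".0"
    for col, (kind, allow_missing) in COLUMN_SPEC.items():
        if kind == "int" and allow_missing:
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False, float_format="%.10g")


def validate_cohort(table: CohortTable) -> ValidationReport:
    """Check per-row invariants without mutating the table.

    Checks: unique ids; categorical levels; BMI consistency with measured
    weight/height (|bmi - w/h^2| <= 0.05); BMI category consistent with BMI;
    nested child flags (obesity implies overweight/obesity) and agreement
    with the z-score thresholds (+1.04 / +1.65); plausibility ranges for
    maternal age, birthweight and gestational age; missingness only where
    allowed.
    """
    df = table.df
    report = ValidationReport()

    dup = df["id"][df["id"].duplicated(keep=False)]
    for rid in sorted(set(dup)):
        rows = df.index[df["id"] == rid].tolist()
        report.violations.append(
            Violation(rid, "id", f"duplicated id in rows {rows}")
        )

    def flag(mask: pd.Series, fld: str, msg: str) -> None:
        for i in df.index[mask.fillna(False)]:
            report.violations.append(Violation(str(df.at[i, "id"]), fld, msg))

    flag(~df["age_p1"].between(12, 60, inclusive="neither"), "age_p1",
         "maternal age outside (12, 60) years")
    for p in ("p1", "p2"):
        bmi, w, h = df[f"{p}_bmi"], df[f"{p}_weight_kg"], df[f"{p}_height_m"]
        flag((bmi - w / h**2).abs() > 0.05, f"{p}_bmi",
             "bmi inconsistent with weight/height^2")
        cat = df[f"{p}_bmi_category"]
        from .derivations import categorize_bmi_array

        ok = bmi >= 18.5
        expected = pd.Series(np.where(ok, categorize_bmi_array(bmi.clip(lower=18.5)), ""),
                             index=df.index)
        flag(ok & (cat != expected), f"{p}_bmi_category",
             "category inconsistent with bmi")
        flag(df[f"{p}_gestation_at_ana_days"] < 0, f"{p}_gestation_at_ana_days",
             "negative gestation at first antenatal appointment")
    for b in ("b1", "b2"):
        flag(df[f"{b}_birthweight_g"] <= 0, f"{b}_birthweight_g",
             "non-positive birthweight")
    flag((df["c2_obesity"] == 1) & (df["c2_overweight_obesity"] == 0),
         "c2_obesity", "obesity flagged without overweight/obesity")
    flag((df["c2_zscore"] >= 1.04) != (df["c2_overweight_obesity"] == 1),
         "c2_overweight_obesity", "flag inconsistent with z-score threshold 1.04")
    flag((df["c2_zscore"] >= 1.65) != (df["c2_obesity"] == 1),
         "c2_obesity", "flag inconsistent with z-score threshold 1.65")
    flag(~df["c2_age_years"].between(4.0, 5.0), "c2_age_years",
         "child measurement age outside [4, 5] years")
    return report


RESULT_COLUMNS = (
    "stratum", "scenario", "description", "outcome",
    "prevalence_pct", "prevalence_lo", "prevalence_hi",
    "risk_ratio", "rr_lo", "rr_hi",
    "mean_difference", "md_lo", "md_hi", "B",
)


def write_results(table, path) -> None:
    """Write an effect table to CSV, one row per (stratum, scenario,
    outcome definition), percentages and ratios rendered to 2 decimals.

    ``table`` is an :class:`pregformula.effects.EffectTable`.  An empty
    table raises rather than writing an empty file.
    """
    df = table.df
    if df is None or len(df) == 0:
        raise ValueError("refusing to write an empty effect table")
    out = df.loc[:, list(RESULT_COLUMNS)].copy()
    for col in RESULT_COLUMNS[4:-1]:
        out[col] = out[col].map(lambda v: f"{v:.2f}")
    out.to_csv(path, index=False)


def cohort_from_frame(df: pd.DataFrame, provenance: str = "") -> CohortTable:
    """Wrap an in-memory DataFrame already in the cohort schema."""
    return CohortTable(df, provenance)
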