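"""Derived quantities and eligibility filtering.

Covers maternal BMI and its WHO-style categories, interpregnancy
weight-change categories, child BMI z-scores against a pluggable growth
reference (normal or LMS parameterisation), the child adiposity flags
(overweight/obesity at the 85th centile, obesity at the 95th), and the
ordered eligibility cascade applied before analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .cohort_io import CohortTable

#: z-score thresholds for the 85th and 95th reference centiles
OVERWEIGHT_Z = 1.04
OBESITY_Z = 1.65

#: eligible gestational-age window for a live birth, in days (22-43 weeks)
GESTATION_MIN_DAYS = 154
GESTATION_MAX_DAYS = 301

#: latest eligible first antenatal appointment, in days (24 weeks)
ANA_MAX_DAYS = 168


class WeightChangeCategory(str, Enum):
    stable = "stable"
    loss = "loss"
    moderate_gain = "moderate_gain"
    high_gain = "high_gain"


class UnderweightError(ValueError):
    """BMI below 18.5 reached the categoriser; eligibility filtering failed."""


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m^2, from measured weight (kg) and height (m)."""
    if weight <= 0 or height <= 0:
        raise ValueError(f"weight and height must be positive, got ({weight}, {height})")
    return weight / height**2


def categorize_bmi(bmi: float) -> str:
    """Map BMI to healthy [18.5, 25) / overweight [25, 30) / obese [30, inf).

    Underweight values signal an upstream eligibility bug and raise.
    """
    if bmi < 18.5:
        raise UnderweightError(f"bmi {bmi} < 18.5; underweight rows are excluded upstream")
    if bmi < 25.0:
        return "healthy"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def categorize_bmi_array(bmi) -> np.ndarray:
    """Vectorised :func:`categorize_bmi`."""
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi < 18.5):
        raise UnderweightError("bmi below 18.5 present; underweight rows are excluded upstream")
    out = np.where(bmi < 25.0, "healthy", np.where(bmi < 30.0, "overweight", "obese"))
    return out


def weight_change_category(bmi_p1: float, bmi_p2: float) -> WeightChangeCategory:
    """Interpregnancy BMI-change category from the two pregnancy-start BMIs.

    loss: change <= -1; stable: within (-1, 1); moderate gain: [1, 3);
    high gain: >= 3 kg/m^2.  At exactly +/-1 the gain/loss rule wins.
    """
    if bmi_p1 < 18.5 or bmi_p2 < 18.5:
        raise UnderweightError("both BMIs must be >= 18.5")
    delta = bmi_p2 - bmi_p1
    if delta <= -1.0:
        return WeightChangeCategory.loss
    if delta < 1.0:
        return WeightChangeCategory.stable
    if delta < 3.0:
        return WeightChangeCategory.moderate_gain
    return WeightChangeCategory.high_gain


@dataclass
class GrowthReference:
    """Age- and sex-specific BMI reference for z-score conversion.

    ``kind`` is ``"normal"`` (entries map (sex, age) -> (mean, sd)) or
    ``"lms"`` (entries map (sex, age) -> (L, M, S)).  Lookup linearly
    interpolates between tabulated ages within sex, clamping at the ends.
    """

    kind: str
    entries: dict[tuple[str, float], tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "lms"):
            raise ValueError(f"unknown reference kind {self.kind!r}")
        for key, vals in self.entries.items():
            if self.kind == "normal":
                mean, sd = vals
                if sd <= 0:
                    raise ValueError(f"sd must be positive at {key}")
            else:
                _, m, s = vals
                if m <= 0 or s <= 0:
                    raise ValueError(f"M and S must be positive at {key}")

    def lookup(self, sex: str, age: float) -> tuple[float, ...]:
        ages = sorted(a for (s, a) in self.entries if s == sex)
        if not ages:
            raise KeyError(f"no reference entries for sex {sex!r}")
        if age <= ages[0]:
            return self.entries[(sex, ages[0])]
        if age >= ages[-1]:
            return self.entries[(sex, ages[-1])]
        hi = next(a for a in ages if a >= age)
        lo = max(a for a in ages if a <= age)
        if hi == lo:
            return self.entries[(sex, lo)]
        w = (age - lo) / (hi - lo)
        lo_v, hi_v = self.entries[(sex, lo)], self.entries[(sex, hi)]
        return tuple((1 - w) * a + w * b for a, b in zip(lo_v, hi_v))

    @classmethod
    def from_lms_csv(cls, path) -> "GrowthReference":
        """Read an LMS reference table (columns: sex, age_years, L, M, S)."""
        df = pd.read_csv(path)
        required = {"sex", "age_years", "L", "M", "S"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"LMS reference missing column(s): {sorted(missing)}")
        entries = {
            (str(r.sex), float(r.age_years)): (float(r.L), float(r.M), float(r.S))
            for r in df.itertuples()
        }
        return cls(kind="lms", entries=entries)


def synthetic_normal_reference(mean: float = 16.0, sd: float = 1.3) -> GrowthReference:
    """A flat normal BMI reference for ages 4-5 (synthetic stand-in).

    This is not a published growth reference; it exists so the package runs
    without external downloads.  Real analyses should load an LMS table via
    :meth:`GrowthReference.from_lms_csv`.
    """
    entries = {}
    for sex in ("M", "F"):
        for age in (4.0, 5.0):
            entries[(sex, age)] = (mean, sd)
    return GrowthReference(kind="normal", entries=entries)


def bmi_zscore(bmi: float, sex: str, age: float, ref: GrowthReference) -> float:
    """Age- and sex-adjusted BMI z-score against a growth reference.

    Normal references use (bmi - mean) / sd.  LMS references use the
    Cole transformation ((bmi/M)^L - 1) / (L*S), with the limiting form
    ln(bmi/M)/S as L -> 0.
    """
    vals = ref.lookup(sex, age)
    if ref.kind == "normal":
        mean, sd = vals
        return (bmi - mean) / sd
    L, M, S = vals
    if abs(L) < 1e-8:
        return float(np.log(bmi / M) / S)
    return float(((bmi / M) ** L - 1.0) / (L * S))


def classify_child(z: float) -> tuple[bool, bool]:
    """(overweight/obesity, obesity) flags from a BMI z-score.

    Overweight/obesity is z >= +1.04 (85th centile); obesity is
    z >= +1.65 (95th centile), so obesity implies overweight/obesity.
    """
    if not np.isfinite(z):
        raise ValueError(f"z-score must be finite, got {z}")
    return bool(z >= OVERWEIGHT_Z), bool(z >= OBESITY_Z)


# ---------------------------------------------------------------------------
# Eligibility cascade

#: rule id -> human-readable description, in application order
ELIGIBILITY_RULES = {
    "late_ana": "first antenatal appointment after 168 days in either pregnancy",
    "underweight": "BMI below 18.5 kg/m^2 at the start of either pregnancy",
    "art": "either pregnancy conceived through assisted reproduction",
    "gestation": "birth gestational age below 154 or above 301 days",
    "child2_measurement": "second-child measurement missing or outside age 4-5",
}


@dataclass
class ExclusionCounts:
    counts: dict[str, int]
    n_input: int
    n_retained: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "exclusions": [
                    {"rule": rule, "description": ELIGIBILITY_RULES[rule], "n": self.counts[rule]}
                    for rule in ELIGIBILITY_RULES
                ],
                "n_retained": self.n_retained,
            },
            indent=2,
        )


def apply_eligibility(table: CohortTable) -> tuple[CohortTable, ExclusionCounts]:
    """Apply the ordered exclusion cascade; each row counts once, at its
    first failing rule.

    Order: late first antenatal appointment (> 168 days, either pregnancy);
    underweight BMI (< 18.5, either pregnancy); assisted reproduction
    (either pregnancy); implausible birth gestation (outside 154-301 days,
    either birth); missing or out-of-window (age 4-5) second-child
    measurement.
    """
    df = table.df
    rules = {
        "late_ana": (df["p1_gestation_at_ana_days"] > ANA_MAX_DAYS)
        | (df["p2_gestation_at_ana_days"] > ANA_MAX_DAYS),
        "underweight": (df["p1_bmi"] < 18.5) | (df["p2_bmi"] < 18.5),
        "art": (df["p1_art"] == 1) | (df["p2_art"] == 1),
        "gestation": ~df["b1_gestational_age_days"].between(GESTATION_MIN_DAYS, GESTATION_MAX_DAYS)
        | ~df["b2_gestational_age_days"].between(GESTATION_MIN_DAYS, GESTATION_MAX_DAYS),
        "child2_measurement": df["c2_bmi"].isna() | ~df["c2_age_years"].between(4.0, 5.0),
    }
    excluded = pd.Series(False, index=df.index)
    counts: dict[str, int] = {}
    for rule, mask in rules.items():
        mask = mask.fillna(True) if rule == "child2_measurement" else mask.fillna(False)
        newly = mask & ~excluded
        counts[rule] = int(newly.sum())
        excluded |= mask
    kept = CohortTable(df.loc[~excluded].reset_index(drop=True), table.provenance)
    return kept, ExclusionCounts(counts, n_input=len(df), n_retained=len(kept))
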