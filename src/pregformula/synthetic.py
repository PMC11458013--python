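"""Synthetic two-pregnancy cohort generator with known ground truth.

Real linked maternity/child-measurement records are not publicly
deposited, so all testing runs on cohorts drawn from an explicit
structural model whose marginals are calibrated to the published cohort
description: three first-pregnancy BMI strata (healthy/overweight/obese,
60.7% / 26.1% / 13.1%), stratum-specific covariate means and SDs,
interpregnancy BMI-change and smoking-transition distributions, and
stratum-specific child adiposity prevalences.

The child outcome is generated as a latent BMI z-score,

    z = alpha_stratum + b_ow * 1[bmi2 overweight] + b_ob * 1[bmi2 obese]
        + b_smk * smoking2 + eps,   eps ~ N(0, 1),

thresholded at +1.04 (overweight/obesity) and +1.65 (obesity), so both
outcome definitions derive from one latent variable and obesity always
implies overweight/obesity.  The stratum intercepts ``alpha`` are
calibrated by root-finding so the factual stratum prevalences of
overweight/obesity match their targets.  Because the structural model is
explicit, true counterfactual prevalences under any static intervention
are computable to Monte-Carlo precision and serve as ground truth for the
estimation engine.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort_io import (
    BMI_CATEGORIES,
    EDUCATIONS,
    ETHNICITIES,
    CohortTable,
)
from .derivations import OBESITY_Z, OVERWEIGHT_Z, categorize_bmi_array
from .scenarios import DEFAULT_SCENARIOS, ScenarioSpec

STRATA = BMI_CATEGORIES  # pregnancy-1 BMI category labels, in order
_BMI_BOUNDS = ((18.5, 25.0), (25.0, 30.0), (30.0, 60.0))

#: BMI-change component shapes per weight-change category: stable and
#: moderate gain are uniform on their ranges; loss is -1 - Exp(scale) so
#: large losses (an obese-stratum mother reaching the healthy range) have
#: positive probability, matching the observed category-transition rates;
#: high gain is 3 + Exp(scale) capped.
_DELTA_RANGES = {
    "stable": (-1.0, 1.0),
    "moderate_gain": (1.0, 3.0),
}
_LOSS_SCALE = 2.75
_HIGH_GAIN_SCALE = 1.5
_HIGH_GAIN_CAP = 10.0

OUTCOMES = ("overweight_obesity", "obesity")
_THRESHOLDS = {"overweight_obesity": OVERWEIGHT_Z, "obesity": OBESITY_Z}


def _norm_rows(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a / a.sum(axis=-1, keepdims=True)


@dataclass
class StructuralParams:
    """The true data-generating mechanism of the synthetic cohort.

    All per-stratum arrays are ordered (healthy, overweight, obese) by
    first-pregnancy BMI category.  Probability vectors must sum to one.
    """

    stratum_probs: np.ndarray
    bmi1_mean: np.ndarray
    bmi1_sd: np.ndarray
    age_mean: np.ndarray
    age_sd: np.ndarray
    sbp1_mean: np.ndarray
    sbp1_sd: np.ndarray
    sbp2_mean: np.ndarray
    sbp2_sd: np.ndarray
    sbp_corr: float
    smoking1: np.ndarray
    smoking2_marginal: np.ndarray
    smoking_start: float  # P(smoking at p2 | not smoking at p1)
    ethnicity_probs: np.ndarray  # (3, 7)
    education_probs: np.ndarray  # (3, 3)
    employed: np.ndarray
    interval_probs: np.ndarray  # (3, 4) over interval categories
    weight_change_probs: np.ndarray  # (3, 4) over (stable, loss, moderate, high)
    birthweight1_mean: np.ndarray
    birthweight1_sd: np.ndarray
    birthweight2_mean: np.ndarray
    birthweight2_sd: np.ndarray
    caesarean1: np.ndarray
    caesarean2: np.ndarray
    missing_sbp1: float
    missing_sbp2: float
    missing_caes1: float
    missing_caes2: float
    beta_overweight: float
    beta_obese: float
    beta_smoking: float
    stratum_intercepts: np.ndarray | None  # set by calibrate()
    child_ref_mean: float
    child_ref_sd: float
    male_prob: float
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stratum_probs", "ethnicity_probs", "education_probs",
                     "interval_probs", "weight_change_probs"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.allclose(v.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
            setattr(self, name, v)
        for name in ("bmi1_sd", "age_sd", "sbp1_sd", "sbp2_sd",
                     "birthweight1_sd", "birthweight2_sd"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")

    @property
    def smoking_persist(self) -> np.ndarray:
        """P(smoking at p2 | smoking at p1), per stratum, implied by the
        pregnancy-1/pregnancy-2 smoking marginals and the start rate."""
        m1, m2 = self.smoking1, self.smoking2_marginal
        p = (m2 - self.smoking_start * (1.0 - m1)) / m1
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("smoking marginals and start rate imply an invalid persistence")
        return p

    def copy(self) -> "StructuralParams":
        return copy.deepcopy(self)

    def to_json(self) -> str:
        def enc(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        return json.dumps({k: enc(v) for k, v in self.__dict__.items()}, indent=2)


#: factual stratum prevalences used as calibration targets, as proportions
CALIBRATION_TARGETS = {
    "overweight_obesity": np.array([0.1719, 0.2585, 0.3813]),
    "obesity": np.array([0.0584, 0.1023, 0.1764]),
}

_DEFAULT_CACHE: StructuralParams | None = None


def _uncalibrated_defaults() -> StructuralParams:
    return StructuralParams(
        stratum_probs=np.array([3409, 1466, 737], dtype=float) / 5612.0,
        bmi1_mean=np.array([22.0, 27.0, 34.3]),
        bmi1_sd=np.array([1.7, 1.4, 4.0]),
        age_mean=np.array([25.9, 26.1, 26.1]),
        age_sd=np.array([5.5, 5.2, 5.2]),
        sbp1_mean=np.array([108.7, 112.4, 117.7]),
        sbp1_sd=np.array([10.6, 10.5, 10.8]),
        sbp2_mean=np.array([107.7, 112.0, 117.0]),
        sbp2_sd=np.array([10.2, 10.4, 10.7]),
        sbp_corr=0.5,
        smoking1=np.array([0.148, 0.147, 0.170]),
        smoking2_marginal=np.array([0.132, 0.128, 0.160]),
        smoking_start=0.02,
        ethnicity_probs=_norm_rows(
            [
                [87.8, 0.9, 4.6, 1.2, 0.6, 0.7, 4.2],
                [90.3, 0.9, 2.9, 1.7, 0.1, 0.4, 3.8],
                [95.0, 1.1, 0.9, 0.7, 0.0, 0.3, 2.0],
            ]
        ),
        education_probs=_norm_rows(
            [[30.2, 36.6, 33.2], [25.2, 40.5, 34.2], [21.0, 47.2, 31.8]]
        ),
        employed=np.array([0.835, 0.855, 0.871]),
        interval_probs=_norm_rows(
            [[17.5, 38.3, 23.3, 20.9], [14.9, 38.6, 25.8, 20.7], [19.0, 36.9, 24.2, 19.9]]
        ),
        weight_change_probs=_norm_rows(
            [[41.3, 12.7, 30.1, 15.9], [28.8, 20.1, 25.9, 25.3], [23.7, 26.3, 22.9, 27.0]]
        ),
        birthweight1_mean=np.array([3342.0, 3411.0, 3500.0]),
        birthweight1_sd=np.array([510.0, 532.0, 562.0]),
        birthweight2_mean=np.array([3497.0, 3587.0, 3681.0]),
        birthweight2_sd=np.array([501.0, 502.0, 551.0]),
        caesarean1=np.array([0.179, 0.246, 0.319]),
        caesarean2=np.array([0.147, 0.215, 0.280]),
        missing_sbp1=0.010,
        missing_sbp2=0.018,
        missing_caes1=0.002,
        missing_caes2=0.014,
        beta_overweight=0.12,
        beta_obese=0.25,
        beta_smoking=0.25,
        stratum_intercepts=None,
        child_ref_mean=16.0,
        child_ref_sd=1.3,
        male_prob=0.512,
        seed=0,
    )


def default_params() -> StructuralParams:
    """Default structural parameters, calibrated so factual stratum
    prevalences of child overweight/obesity match the targets in
    :data:`CALIBRATION_TARGETS`."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        _DEFAULT_CACHE = calibrate(_uncalibrated_defaults())
    return _DEFAULT_CACHE.copy()


def _draw_stratum_p2(params: StructuralParams, s: int, n: int, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw (smoking1, smoking2, bmi1, bmi2) for n mothers in stratum s."""
    lo, hi = _BMI_BOUNDS[s]
    a = (lo - params.bmi1_mean[s]) / params.bmi1_sd[s]
    b = (hi - params.bmi1_mean[s]) / params.bmi1_sd[s]
    bmi1 = stats.truncnorm.rvs(a, b, loc=params.bmi1_mean[s], scale=params.bmi1_sd[s],
                               size=n, random_state=rng)
    smoking1 = (rng.random(n) < params.smoking1[s]).astype(int)
    p_next = np.where(smoking1 == 1, params.smoking_persist[s], params.smoking_start)
    smoking2 = (rng.random(n) < p_next).astype(int)
    delta = _draw_delta(params, s, n, rng)
    bmi2 = np.maximum(bmi1 + delta, 18.51)
    return smoking1, smoking2, bmi1, bmi2


def _draw_delta(params: StructuralParams, s: int, n: int, rng) -> np.ndarray:
    cats = rng.choice(4, size=n, p=params.weight_change_probs[s])
    delta = np.empty(n)
    for i, name in ((0, "stable"), (2, "moderate_gain")):
        lo, hi = _DELTA_RANGES[name]
        m = cats == i
        delta[m] = rng.uniform(lo, hi, size=int(m.sum()))
    m = cats == 1
    delta[m] = -1.0 - rng.exponential(_LOSS_SCALE, size=int(m.sum()))
    m = cats == 3
    delta[m] = 3.0 + np.minimum(
        rng.exponential(_HIGH_GAIN_SCALE, size=int(m.sum())), _HIGH_GAIN_CAP - 3.0
    )
    return delta


def _linear_predictor(params: StructuralParams, bmi2_cat: np.ndarray, smoking2: np.ndarray) -> np.ndarray:
    return (
        params.beta_overweight * (bmi2_cat == "overweight")
        + params.beta_obese * (bmi2_cat == "obese")
        + params.beta_smoking * smoking2
    )


def calibrate(
    params: StructuralParams,
    targets: np.ndarray | None = None,
    n_mc: int = 100_000,
    seed: int = 202_410,
) -> StructuralParams:
    """Solve for the stratum intercepts of the latent-z outcome model.

    For each stratum, 1-d root-finding (Brent) on the intercept alpha so
    the implied factual prevalence of overweight/obesity,

        E[ 1 - Phi(1.04 - alpha - b.x) ]

    over a fixed Monte-Carlo draw of pregnancy-2 covariates x, matches the
    target.  The implied prevalence is strictly increasing in alpha, so
    the root is unique; the obesity prevalence then follows from the same
    latent variable.
    """
    if targets is None:
        targets = CALIBRATION_TARGETS["overweight_obesity"]
    targets = np.asarray(targets, dtype=float)
    if np.any((targets <= 0) | (targets >= 1)):
        raise ValueError("calibration targets must lie strictly inside (0, 1)")
    out = params.copy()
    intercepts = np.empty(3)
    rng = np.random.default_rng(seed)
    for s in range(3):
        _, smoking2, _, bmi2 = _draw_stratum_p2(params, s, n_mc, rng)
        bx = _linear_predictor(params, categorize_bmi_array(bmi2), smoking2)

        def implied(alpha: float) -> float:
            return float(np.mean(stats.norm.sf(OVERWEIGHT_Z - alpha - bx)))

        try:
            intercepts[s] = optimize.brentq(
                lambda a: implied(a) - targets[s], -8.0, 8.0, xtol=1e-10
            )
        except ValueError as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"calibration failed for stratum {STRATA[s]}: "
                f"target {targets[s]} not bracketed ({exc})"
            ) from exc
        achieved = implied(intercepts[s])
        if abs(achieved - targets[s]) > 1e-3:  # 0.1 percentage points
            raise RuntimeError(
                f"calibration for stratum {STRATA[s]} off target: "
                f"{achieved:.5f} vs {targets[s]:.5f}"
            )
    out.stratum_intercepts = intercepts
    return out


def _choice_by_stratum(rng, stratum: np.ndarray, probs: np.ndarray, labels) -> np.ndarray:
    """Per-row categorical draw with stratum-specific probability rows."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(stratum))
    idx = (u[:, None] > cum[stratum]).sum(axis=1)
    return np.asarray(labels, dtype=object)[idx]


_INTERVAL_BOUNDS = ((3.0, 12.0), (12.0, 24.0), (24.0, 36.0), (36.0, 72.0))


def generate_cohort(params: StructuralParams, n: int, seed: int | None = None) -> CohortTable:
    """Draw a schema-valid cohort of ``n`` mothers from the structural model.

    All eligibility rules are satisfied by construction (no late antenatal
    appointments, no underweight BMIs, no assisted reproduction, birth
    gestations inside 154-301 days, every second child measured at age
    4-5), so the eligibility cascade excludes nothing.
    """
    if params.stratum_intercepts is None:
        raise ValueError("params must be calibrated first (see calibrate())")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    stratum = rng.choice(3, size=n, p=params.stratum_probs)

    def per_stratum_normal(mean, sd):
        return rng.normal(np.asarray(mean)[stratum], np.asarray(sd)[stratum])

    # pregnancy-1 / pregnancy-2 draws, stratum-blocked for the truncated BMI
    smoking1 = np.empty(n, dtype=int)
    smoking2 = np.empty(n, dtype=int)
    bmi1 = np.empty(n)
    bmi2 = np.empty(n)
    for s in range(3):
        m = stratum == s
        smoking1[m], smoking2[m], bmi1[m], bmi2[m] = _draw_stratum_p2(
            params, s, int(m.sum()), rng
        )

    age = np.clip(per_stratum_normal(params.age_mean, params.age_sd), 16.0, 50.0)
    height = np.clip(rng.normal(1.65, 0.07, size=n), 1.45, 1.95)
    sbp1 = per_stratum_normal(params.sbp1_mean, params.sbp1_sd)
    sbp_noise_sd = params.sbp2_sd[stratum] * np.sqrt(1.0 - params.sbp_corr**2)
    sbp2 = (
        params.sbp2_mean[stratum]
        + params.sbp_corr
        * (sbp1 - params.sbp1_mean[stratum])
        * params.sbp2_sd[stratum]
        / params.sbp1_sd[stratum]
        + rng.normal(0.0, sbp_noise_sd)
    )
    ethnicity = _choice_by_stratum(rng, stratum, params.ethnicity_probs, ETHNICITIES)
    education = _choice_by_stratum(rng, stratum, params.education_probs, EDUCATIONS)
    employed = (rng.random(n) < params.employed[stratum]).astype(int)
    interval_cat = (rng.random(n)[:, None] > np.cumsum(params.interval_probs, axis=1)[stratum]).sum(axis=1)
    lo = np.array([b[0] for b in _INTERVAL_BOUNDS])[interval_cat]
    hi = np.array([b[1] for b in _INTERVAL_BOUNDS])[interval_cat]
    interval = rng.uniform(lo, hi)

    ana1 = rng.uniform(56.0, 126.0, size=n)
    ana2 = rng.uniform(56.0, 126.0, size=n)
    ga1 = stats.truncnorm.rvs(
        (154 - 280) / 12.0, (301 - 280) / 12.0, loc=280.0, scale=12.0, size=n, random_state=rng
    )
    ga2 = stats.truncnorm.rvs(
        (154 - 280) / 10.0, (301 - 280) / 10.0, loc=280.0, scale=10.0, size=n, random_state=rng
    )
    bw1 = np.clip(per_stratum_normal(params.birthweight1_mean, params.birthweight1_sd), 500, 6500)
    bw2 = np.clip(per_stratum_normal(params.birthweight2_mean, params.birthweight2_sd), 500, 6500)
    caes1 = (rng.random(n) < params.caesarean1[stratum]).astype(float)
    caes2 = (rng.random(n) < params.caesarean2[stratum]).astype(float)

    bmi2_cat = categorize_bmi_array(bmi2)
    z = (
        params.stratum_intercepts[stratum]
        + _linear_predictor(params, bmi2_cat, smoking2)
        + rng.normal(size=n)
    )
    sex = np.where(rng.random(n) < params.male_prob, "M", "F")
    child_age = rng.uniform(4.0, 5.0, size=n)
    c2_bmi = params.child_ref_mean + z * params.child_ref_sd

    sbp1 = np.where(rng.random(n) < params.missing_sbp1, np.nan, sbp1)
    sbp2 = np.where(rng.random(n) < params.missing_sbp2, np.nan, sbp2)
    caes1 = np.where(rng.random(n) < params.missing_caes1, np.nan, caes1)
    caes2 = np.where(rng.random(n) < params.missing_caes2, np.nan, caes2)

    df = pd.DataFrame(
        {
            "id": [f"m{i:06d}" for i in range(n)],
            "age_p1": np.round(age, 4),
            "ethnicity": ethnicity,
            "education": education,
            "employed": employed,
            "interpregnancy_interval_months": np.round(interval, 4),
            "p1_gestation_at_ana_days": np.round(ana1, 1),
            "p1_weight_kg": np.round(bmi1 * height**2, 4),
            "p1_height_m": np.round(height, 4),
            "p1_bmi": np.round(bmi1, 4),
            "p1_bmi_category": categorize_bmi_array(bmi1),
            "p1_smoking": smoking1,
            "p1_sbp": np.round(sbp1, 2),
            "p1_art": np.zeros(n, dtype=int),
            "p2_gestation_at_ana_days": np.round(ana2, 1),
            "p2_weight_kg": np.round(bmi2 * height**2, 4),
            "p2_height_m": np.round(height, 4),
            "p2_bmi": np.round(bmi2, 4),
            "p2_bmi_category": bmi2_cat,
            "p2_smoking": smoking2,
            "p2_sbp": np.round(sbp2, 2),
            "p2_art": np.zeros(n, dtype=int),
            "b1_birthweight_g": np.round(bw1, 0),
            "b1_gestational_age_days": np.round(ga1, 0),
            "b1_caesarean": caes1,
            "b2_birthweight_g": np.round(bw2, 0),
            "b2_gestational_age_days": np.round(ga2, 0),
            "b2_caesarean": caes2,
            "c2_sex": sex,
            "c2_age_years": np.round(child_age, 4),
            "c2_bmi": np.round(c2_bmi, 6),
            "c2_zscore": np.round(z, 6),
            "c2_overweight_obesity": (z >= OVERWEIGHT_Z).astype(int),
            "c2_obesity": (z >= OBESITY_Z).astype(int),
        }
    )
    # rounding of p1_bmi may not flip categories (bounds are far from the
    # 4-dp rounding error) but weight is re-derived so the bmi invariant holds
    df["p1_weight_kg"] = np.round(df["p1_bmi"] * df["p1_height_m"] ** 2, 4)
    df["p2_weight_kg"] = np.round(df["p2_bmi"] * df["p2_height_m"] ** 2, 4)
    # keep flags consistent with the rounded stored z-score
    df["c2_overweight_obesity"] = (df["c2_zscore"] >= OVERWEIGHT_Z).astype(int)
    df["c2_obesity"] = (df["c2_zscore"] >= OBESITY_Z).astype(int)
    return CohortTable(df, provenance=f"synthetic cohort, n={n}")


def true_counterfactual_prevalence(
    params: StructuralParams,
    scenario: ScenarioSpec,
    n_mc: int = 200_000,
    seed: int = 7,
    outcome: str = "overweight_obesity",
) -> float:
    """Ground-truth prevalence under a scenario, by simulating the
    structural model with the intervention applied at the structural level.
    """
    if params.stratum_intercepts is None:
        raise ValueError("params must be calibrated first")
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    rng = np.random.default_rng(seed)
    stratum = rng.choice(3, size=n_mc, p=params.stratum_probs)
    smoking2 = np.empty(n_mc, dtype=int)
    bmi2 = np.empty(n_mc)
    for s in range(3):
        m = stratum == s
        _, smoking2[m], _, bmi2[m] = _draw_stratum_p2(params, s, int(m.sum()), rng)
    if scenario.bmi_intervention is not None:
        bmi2_cat = np.full(n_mc, scenario.bmi_intervention, dtype=object)
    else:
        bmi2_cat = categorize_bmi_array(bmi2)
    if scenario.smoking_cessation:
        smoking2 = np.zeros(n_mc, dtype=int)
    mu = params.stratum_intercepts[stratum] + _linear_predictor(params, bmi2_cat, smoking2)
    # integrate the N(0,1) latent noise analytically: E[1 - Phi(c - mu)]
    return float(np.mean(stats.norm.sf(_THRESHOLDS[outcome] - mu)))


@dataclass
class TruthTable:
    """True counterfactual prevalences per (scenario, outcome)."""

    values: dict[int, dict[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.values, indent=2)


def truth_table(
    params: StructuralParams,
    scenarios=DEFAULT_SCENARIOS,
    n_mc: int = 200_000,
    seed: int = 7,
) -> TruthTable:
    tt = TruthTable()
    for sc in scenarios:
        tt.values[sc.id] = {
            outc: true_counterfactual_prevalence(params, sc, n_mc=n_mc, seed=seed, outcome=outc)
            for outc in OUTCOMES
        }
    return tt
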