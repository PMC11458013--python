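"""Exact standardization on fully discrete joint distributions.

On a discrete data-generating process the g-formula has a closed form:

    prev(scenario) = sum_b P(b) * sum_x P(x | b, overrides) * risk(b, x)

with b the baseline covariates, x the pregnancy-2 covariates, and each
intervened covariate's conditional replaced by a point mass at the
intervened value.  This module evaluates that sum exactly and is the
independent oracle against which the Monte-Carlo engine is verified.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from .cohort_io import CohortTable
from .engine import ModelConfig, run_gformula
from .scenarios import ScenarioSpec


class DiscreteJoint:
    """A discrete joint over baseline and pregnancy-2 covariates plus a
    conditional outcome risk per cell.

    ``probs`` and ``risks`` are arrays of shape
    (baseline level counts..., pregnancy-2 level counts...); probs must
    sum to one and risks lie in [0, 1].
    """

    def __init__(
        self,
        baseline_vars: dict[str, tuple],
        p2_vars: dict[str, tuple],
        probs: np.ndarray,
        risks: np.ndarray,
    ):
        self.baseline_vars = {k: tuple(v) for k, v in baseline_vars.items()}
        self.p2_vars = {k: tuple(v) for k, v in p2_vars.items()}
        shape = tuple(len(v) for v in self.baseline_vars.values()) + tuple(
            len(v) for v in self.p2_vars.values()
        )
        self.probs = np.asarray(probs, dtype=float).reshape(shape)
        self.risks = np.asarray(risks, dtype=float).reshape(shape)
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("cell probabilities must sum to 1 within 1e-12")
        if np.any(self.probs < 0):
            raise ValueError("cell probabilities must be non-negative")
        if np.any((self.risks < 0) | (self.risks > 1)):
            raise ValueError("risks must lie in [0, 1]")

    @property
    def n_baseline(self) -> int:
        return len(self.baseline_vars)

    def to_json(self) -> str:
        return json.dumps(
            {
                "baseline_vars": {k: list(v) for k, v in self.baseline_vars.items()},
                "p2_vars": {k: list(v) for k, v in self.p2_vars.items()},
                "probs": self.probs.ravel().tolist(),
                "risks": self.risks.ravel().tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "DiscreteJoint":
        d = json.loads(s)
        return cls(d["baseline_vars"], d["p2_vars"], d["probs"], d["risks"])


def _overrides(joint: DiscreteJoint, scenario: ScenarioSpec) -> dict[str, object]:
    out: dict[str, object] = {}
    if scenario.bmi_intervention is not None:
        out["bmi2_category"] = scenario.bmi_intervention
    if scenario.smoking_cessation:
        out["smoking2"] = 0
    for var, value in out.items():
        if var not in joint.p2_vars:
            raise ValueError(f"intervention variable {var!r} not in the joint")
        if value not in joint.p2_vars[var]:
            raise ValueError(f"value {value!r} outside the support of {var!r}")
    return out


def exact_standardization(joint: DiscreteJoint, scenario: ScenarioSpec) -> float:
    """Closed-form standardized outcome prevalence under a static scenario."""
    nb = joint.n_baseline
    p2_axes = tuple(range(nb, joint.probs.ndim))
    p_baseline = joint.probs.sum(axis=p2_axes)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = joint.probs / p_baseline.reshape(p_baseline.shape + (1,) * len(p2_axes))
    cond = np.nan_to_num(cond)  # empty baseline strata contribute zero mass
    for var, value in _overrides(joint, scenario).items():
        ax = nb + list(joint.p2_vars).index(var)
        marginal = cond.sum(axis=ax, keepdims=True)
        point = np.zeros(joint.probs.shape[ax])
        point[joint.p2_vars[var].index(value)] = 1.0
        shape = [1] * joint.probs.ndim
        shape[ax] = -1
        cond = marginal * point.reshape(shape)
    inner = (cond * joint.risks).sum(axis=p2_axes)
    return float((p_baseline * inner).sum())


# ---------------------------------------------------------------------------
# Engine comparison on cohorts sampled from the joint

_FILLER = {
    "age_p1": 28.0,
    "ethnicity": "White",
    "education": "College",
    "employed": 1,
    "interpregnancy_interval_months": 18.0,
    "p1_gestation_at_ana_days": 84.0,
    "p1_height_m": 1.65,
    "p1_sbp": 110.0,
    "p1_art": 0,
    "p2_gestation_at_ana_days": 84.0,
    "p2_height_m": 1.65,
    "p2_sbp": 110.0,
    "p2_art": 0,
    "b1_birthweight_g": 3400.0,
    "b1_gestational_age_days": 280.0,
    "b1_caesarean": 0,
    "b2_birthweight_g": 3500.0,
    "b2_gestational_age_days": 280.0,
    "b2_caesarean": 0,
    "c2_sex": "F",
    "c2_age_years": 4.5,
}

_CAT_BMI = {"healthy": 22.0, "overweight": 27.0, "obese": 33.0}


def sample_cohort(joint: DiscreteJoint, n: int, seed: int = 0) -> CohortTable:
    """Sample a schema-valid cohort from the joint.

    The joint's variables must be drawn from {smoking1, bmi1_category}
    (baseline) and {smoking2, bmi2_category} (pregnancy 2); all other
    cohort columns are constant fillers.  The overweight/obesity flag is
    Bernoulli in each cell's risk; the obesity flag is nested consistently.
    """
    known = {"smoking1", "bmi1_category", "smoking2", "bmi2_category"}
    names = list(joint.baseline_vars) + list(joint.p2_vars)
    unknown = set(names) - known
    if unknown:
        raise ValueError(f"cannot map joint variable(s) {sorted(unknown)} onto the cohort schema")
    rng = np.random.default_rng(seed)
    flat = joint.probs.ravel()
    cells = rng.choice(len(flat), size=n, p=flat)
    grid = np.array(np.unravel_index(cells, joint.probs.shape)).T
    levels = list(joint.baseline_vars.values()) + list(joint.p2_vars.values())
    values = {
        name: np.asarray(lv, dtype=object)[grid[:, j]]
        for j, (name, lv) in enumerate(zip(names, levels))
    }
    risk = joint.risks.ravel()[cells]
    ow = (rng.random(n) < risk).astype(int)

    df = pd.DataFrame({"id": [f"o{i:06d}" for i in range(n)]})
    for col, val in _FILLER.items():
        df[col] = val
    bmi1_cat = values.get("bmi1_category", np.full(n, "healthy", dtype=object))
    bmi2_cat = values.get("bmi2_category", np.full(n, "healthy", dtype=object))
    df["p1_bmi_category"] = bmi1_cat
    df["p2_bmi_category"] = bmi2_cat
    df["p1_bmi"] = [_CAT_BMI[c] for c in bmi1_cat]
    df["p2_bmi"] = [_CAT_BMI[c] for c in bmi2_cat]
    df["p1_weight_kg"] = df["p1_bmi"] * df["p1_height_m"] ** 2
    df["p2_weight_kg"] = df["p2_bmi"] * df["p2_height_m"] ** 2
    df["p1_smoking"] = values.get("smoking1", np.zeros(n, dtype=int)).astype(int)
    df["p2_smoking"] = values.get("smoking2", np.zeros(n, dtype=int)).astype(int)
    df["c2_overweight_obesity"] = ow
    df["c2_obesity"] = 0
    df["c2_zscore"] = np.where(ow == 1, 1.5, 0.0)  # consistent with both thresholds
    df["c2_bmi"] = 16.0 + df["c2_zscore"] * 1.3
    return CohortTable(df, provenance="sampled from discrete joint")


def oracle_config(joint: DiscreteJoint, n_copies: int = 10, seed: int = 0) -> ModelConfig:
    """A saturated engine configuration matching the joint's variables."""
    order = tuple(v for v in ("smoking2", "bmi2_category") if v in joint.p2_vars)
    predictors = tuple(v for v in ("bmi1_category", "smoking1") if v in joint.baseline_vars)
    return ModelConfig(
        covariate_order=order,
        predictor_terms=predictors,
        n_copies=n_copies,
        seed=seed,
        saturated=True,
    )


def compare_to_engine(
    joint: DiscreteJoint,
    n: int,
    config: ModelConfig | None = None,
    scenario: ScenarioSpec = ScenarioSpec(0),
    seed: int = 0,
) -> float:
    """|engine estimate - exact standardization| on a cohort of size n
    sampled from the joint.  With saturated models the difference is pure
    sampling/Monte-Carlo error; a non-saturated config adds approximation
    error and triggers a warning."""
    if config is None:
        config = oracle_config(joint, seed=seed)
    if not config.saturated:
        warnings.warn("non-saturated config: difference includes model approximation error")
    # the cohort-sampling stream must be independent of the engine's
    # simulation stream: with a shared seed each subject's sampled cell is
    # a deterministic function of the same uniforms the engine then draws
    cohort_seed = int(np.random.SeedSequence([seed, 911]).generate_state(1)[0] % (2**31))
    cohort = sample_cohort(joint, n, seed=cohort_seed)
    scenarios = (ScenarioSpec(0), scenario) if scenario.id != 0 else (scenario,)
    est = run_gformula(cohort, config, scenarios=scenarios)
    engine_val = est.get(scenario.id, "overweight_obesity")
    return abs(engine_val - exact_standardization(joint, scenario))


def random_joint(rng, max_vars: int = 3, max_levels: int = 3) -> DiscreteJoint:
    """A random small instance (<= 4 variables of <= 4 levels) for
    property tests."""
    n_b = int(rng.integers(1, max_vars))
    n_p = int(rng.integers(1, max_vars))
    pool_b = [("smoking1", (0, 1)), ("bmi1_category", ("healthy", "overweight", "obese"))]
    pool_p = [("smoking2", (0, 1)), ("bmi2_category", ("healthy", "overweight", "obese"))]
    baseline = dict(pool_b[:n_b])
    p2 = dict(pool_p[:n_p])
    shape = tuple(len(v) for v in baseline.values()) + tuple(len(v) for v in p2.values())
    probs = rng.random(shape) + 0.05
    probs /= probs.sum()
    risks = rng.random(shape)
    return DiscreteJoint(baseline, p2, probs, risks)
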