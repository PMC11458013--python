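import numpy as np
import pandas as pd
import pytest

import pregformula as pf
from pregformula.engine import ConfigError, ModelConfig, fit_models, run_gformula, run_stratified
from pregformula.oracle import DiscreteJoint, oracle_config, random_joint, sample_cohort
from pregformula.scenarios import DEFAULT_SCENARIOS, ScenarioSpec


def test_config_rejects_unknown_terms_and_duplicates():
    with pytest.raises(ConfigError):
        ModelConfig(predictor_terms=("not_a_term",))
    with pytest.raises(ConfigError):
        ModelConfig(covariate_order=("smoking2", "smoking2"))
    with pytest.raises(ConfigError):
        # outcome refers to a simulated covariate missing from the causal order
        ModelConfig(covariate_order=("smoking2",), outcome_terms=("smoking1", "sbp2"))


def test_scenarios_must_include_natural_course(cohort_small, light_config):
    with pytest.raises(ConfigError):
        run_gformula(cohort_small, light_config, scenarios=(ScenarioSpec(1, "healthy"),))


def test_constant_outcome_predicts_the_constant():
    joint = DiscreteJoint(
        {"smoking1": (0, 1)}, {"smoking2": (0, 1)},
        np.full((2, 2), 0.25), np.ones((2, 2)),
    )
    cohort = sample_cohort(joint, 500, seed=0)
    cfg = oracle_config(joint, n_copies=3, seed=0)
    est = run_gformula(cohort, cfg, scenarios=(ScenarioSpec(0), ScenarioSpec(4, smoking_cessation=True)))
    for sc in (0, 4):
        assert est.get(sc, "overweight_obesity") == 1.0
        assert est.get(sc, "obesity") == 0.0  # nested flag constant at zero


def test_saturated_fit_reproduces_cell_proportions():
    """On a fully discrete cohort with saturated terms the fitted outcome
    probabilities equal the empirical cell proportions (tabulated
    independently with pandas groupby)."""
    rng = np.random.default_rng(17)
    joint = random_joint(rng, max_vars=3)
    cohort = sample_cohort(joint, 4000, seed=2)
    cfg = oracle_config(joint, seed=0)
    models = fit_models(cohort, cfg)
    df = cohort.df
    colmap = {
        "smoking1": "p1_smoking", "bmi1_category": "p1_bmi_category",
        "smoking2": "p2_smoking", "bmi2_category": "p2_bmi_category",
    }
    enc = models.outcome_encoder
    codes = enc.cell_codes({t: df[colmap[t]].to_numpy() for t in enc.terms})
    fitted_p = models.outcome_models["overweight_obesity"].predict_codes(codes)
    cell_mean = df.groupby(codes, sort=False)["c2_overweight_obesity"].transform("mean")
    np.testing.assert_allclose(fitted_p, cell_mean.to_numpy(), atol=1e-12)


def test_run_is_deterministic_given_seed(cohort_small, light_config):
    a = run_gformula(cohort_small, light_config)
    b = run_gformula(cohort_small, light_config)
    pd.testing.assert_frame_equal(a.df, b.df)
    assert a.df["prevalence"].between(0, 1).all()


def test_default_scenarios_give_sixteen_estimates(cohort_small, light_config):
    est = run_gformula(cohort_small, light_config)
    assert len(est.df) == 16  # 8 scenarios x 2 outcome definitions
    assert set(est.df["scenario"]) == set(range(8))


def test_noop_intervention_reproduces_natural_course_exactly(cohort_small, light_config):
    """Forcing cessation in a cohort with no smokers overwrites each copy's
    simulated value with itself, so common random numbers make the result
    bit-identical to the natural course."""
    df = cohort_small.df.copy()
    df["p1_smoking"] = 0
    df["p2_smoking"] = 0
    table = pf.CohortTable(df)
    est = run_gformula(table, light_config, scenarios=(ScenarioSpec(0), ScenarioSpec(4, smoking_cessation=True)))
    for outcome in ("overweight_obesity", "obesity"):
        assert est.get(4, outcome) == est.get(0, outcome)


def test_null_effect_generator_equalises_scenarios():
    """When the structural outcome model ignores pregnancy-2 BMI and
    smoking, every intervention leaves prevalence at the natural course
    (up to the sampling noise of the fitted exposure coefficients, which
    collinearity with the first-pregnancy category inflates)."""
    params = pf.default_params()
    params.beta_overweight = params.beta_obese = params.beta_smoking = 0.0
    params = pf.calibrate(params)
    cohort = pf.generate_cohort(params, 40_000, seed=3)
    cfg = pf.ModelConfig(
        predictor_terms=("bmi1_category", "smoking1"),
        covariate_order=("smoking2", "bmi2_category"),
        n_copies=2, seed=11,
    )
    est = run_gformula(cohort, cfg)
    p0 = est.get(0, "overweight_obesity")
    for sc in range(1, 8):
        assert est.get(sc, "overweight_obesity") == pytest.approx(p0, abs=0.015)


def test_child_risk_monotone_in_bmi_category(cohort_mid, light_config):
    est = run_gformula(cohort_mid, light_config)
    for outcome in ("overweight_obesity", "obesity"):
        assert est.get(1, outcome) <= est.get(2, outcome) <= est.get(3, outcome)


def test_natural_course_tracks_empirical_prevalence(cohort_mid):
    cfg = ModelConfig(seed=5)
    est = run_gformula(cohort_mid, cfg)
    for outcome, col in (("overweight_obesity", "c2_overweight_obesity"), ("obesity", "c2_obesity")):
        assert est.get(0, outcome) == pytest.approx(cohort_mid.df[col].mean(), abs=0.01)


def test_stratified_runs_fit_within_each_stratum(cohort_mid, light_config):
    out = run_stratified(cohort_mid, light_config)
    assert set(out) == {"healthy", "overweight", "obese"}
    sizes = {k: v.n for k, v in out.items()}
    assert sum(sizes.values()) == len(cohort_mid)
    for label, est in out.items():
        assert est.stratum == label
        assert est.df["prevalence"].between(0, 1).all()
    # stratum prevalences increase with first-pregnancy BMI category
    assert out["healthy"].get(0, "obesity") < out["obese"].get(0, "obesity")


def test_stratified_missing_stratum_is_flagged(cohort_small, light_config):
    df = cohort_small.df[cohort_small.df["p1_bmi_category"] != "obese"]
    table = pf.CohortTable(df.reset_index(drop=True))
    with pytest.warns(UserWarning, match="obese"):
        out = run_stratified(table, light_config)
    assert out["obese"] is None
    assert out["healthy"] is not None


def test_stratified_small_stratum_skipped_with_warning(cohort_small):
    cfg = pf.ModelConfig(
        predictor_terms=("bmi1_category", "smoking1"),
        covariate_order=("smoking2", "bmi2_category"),
        n_copies=5, seed=11, min_stratum_n=5000,
    )
    with pytest.warns(UserWarning):
        out = run_stratified(cohort_small, cfg)
    assert all(v is None for v in out.values())


def test_missing_sbp_rows_are_complete_case_dropped(cohort_mid):
    cfg = ModelConfig(seed=5)
    models = fit_models(cohort_mid, cfg)
    n_missing = int(
        cohort_mid.df[["p1_sbp", "p2_sbp"]].isna().any(axis=1).sum()
    )
    assert models.n_dropped_missing == n_missing
    assert models.n_fit == len(cohort_mid) - n_missing
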