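import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pregformula as pf
from pregformula.derivations import OVERWEIGHT_Z, apply_eligibility, weight_change_category
from pregformula.scenarios import DEFAULT_SCENARIOS, ScenarioSpec
from pregformula.synthetic import (
    CALIBRATION_TARGETS,
    calibrate,
    default_params,
    generate_cohort,
    true_counterfactual_prevalence,
    truth_table,
)


def test_default_stratum_proportions(params):
    np.testing.assert_allclose(
        params.stratum_probs, np.array([3409, 1466, 737]) / 5612, atol=1e-12
    )
    assert params.smoking1[2] == pytest.approx(0.170)


def test_probability_vectors_sum_to_one(params):
    for name in ("stratum_probs", "ethnicity_probs", "education_probs",
                 "interval_probs", "weight_change_probs"):
        v = getattr(params, name)
        np.testing.assert_allclose(np.asarray(v).sum(axis=-1), 1.0, atol=1e-9)


def test_generation_is_deterministic(params):
    a = generate_cohort(params, 500, seed=3)
    b = generate_cohort(params, 500, seed=3)
    pd.testing.assert_frame_equal(a.df, b.df)


def test_generated_cohort_is_schema_valid_and_fully_eligible(params):
    cohort = generate_cohort(params, 2000, seed=9)
    assert pf.validate_cohort(cohort).ok
    kept, counts = apply_eligibility(cohort)
    assert counts.n_retained == 2000
    assert all(v == 0 for v in counts.counts.values())


def test_stratum_sizes_are_multinomial_around_targets(params):
    for seed in (1, 2, 3):
        df = generate_cohort(params, 5612, seed=seed).df
        observed = df["p1_bmi_category"].value_counts()
        obs = [observed.get(c, 0) for c in ("healthy", "overweight", "obese")]
        res = stats.chisquare(obs, f_exp=params.stratum_probs * 5612)
        assert res.pvalue > 0.01


def test_weight_change_frequencies_match_structural_probs(params):
    df = generate_cohort(params, 20_000, seed=4).df
    for s, label in enumerate(("healthy", "overweight", "obese")):
        sub = df[df["p1_bmi_category"] == label]
        cats = [
            weight_change_category(b1, b2).value
            for b1, b2 in zip(sub["p1_bmi"], sub["p2_bmi"])
        ]
        freq = pd.Series(cats).value_counts(normalize=True)
        for j, name in enumerate(("stable", "loss", "moderate_gain", "high_gain")):
            assert freq.get(name, 0.0) == pytest.approx(
                params.weight_change_probs[s, j], abs=0.02
            )


def test_smoking_marginals_match_both_pregnancies(params):
    df = generate_cohort(params, 40_000, seed=6).df
    for s, label in enumerate(("healthy", "overweight", "obese")):
        sub = df[df["p1_bmi_category"] == label]
        assert sub["p1_smoking"].mean() == pytest.approx(params.smoking1[s], abs=0.01)
        assert sub["p2_smoking"].mean() == pytest.approx(params.smoking2_marginal[s], abs=0.01)


def test_calibrated_stratum_prevalences_hit_targets(params):
    df = generate_cohort(params, 50_000, seed=8).df
    for s, label in enumerate(("healthy", "overweight", "obese")):
        sub = df[df["p1_bmi_category"] == label]
        assert sub["c2_overweight_obesity"].mean() == pytest.approx(
            CALIBRATION_TARGETS["overweight_obesity"][s], abs=0.01
        )
        # obesity follows from the same latent z-score without being targeted
        assert sub["c2_obesity"].mean() == pytest.approx(
            CALIBRATION_TARGETS["obesity"][s], abs=0.012
        )


def test_calibrate_identity_with_null_effects():
    """With zero structural effects a 50% target puts the intercept at the
    overweight/obesity threshold itself (symmetric latent noise)."""
    params = default_params()
    params.beta_overweight = params.beta_obese = params.beta_smoking = 0.0
    out = calibrate(params, targets=np.array([0.5, 0.5, 0.5]))
    np.testing.assert_allclose(out.stratum_intercepts, OVERWEIGHT_Z, atol=1e-6)


def test_calibrate_rejects_degenerate_targets(params):
    with pytest.raises(ValueError):
        calibrate(params, targets=np.array([0.0, 0.5, 0.5]))


def test_truth_table_consistency(params):
    tt = truth_table(params, DEFAULT_SCENARIOS, n_mc=100_000, seed=13)
    # scenario 0 matches the generated factual prevalence
    df = generate_cohort(params, 50_000, seed=14).df
    assert tt.values[0]["overweight_obesity"] == pytest.approx(
        df["c2_overweight_obesity"].mean(), abs=0.01
    )
    # assigning progressively higher BMI categories raises true risk
    assert tt.values[1]["obesity"] < tt.values[2]["obesity"] < tt.values[3]["obesity"]
    # nested outcomes
    for sc in tt.values:
        assert tt.values[sc]["obesity"] <= tt.values[sc]["overweight_obesity"]


def test_null_effects_make_counterfactuals_equal_natural_course():
    params = default_params()
    params.beta_overweight = params.beta_obese = params.beta_smoking = 0.0
    params = calibrate(params)
    p0 = true_counterfactual_prevalence(params, ScenarioSpec(0), n_mc=50_000, seed=2)
    p3 = true_counterfactual_prevalence(params, ScenarioSpec(3, "obese"), n_mc=50_000, seed=2)
    assert p3 == pytest.approx(p0, abs=1e-12)


def test_uncalibrated_params_cannot_generate():
    params = default_params()
    params.stratum_intercepts = None
    with pytest.raises(ValueError):
        generate_cohort(params, 10, seed=0)


def test_whole_cohort_prevalence_is_stratum_weighted_average(params):
    df = generate_cohort(params, 20_000, seed=15).df
    whole = df["c2_obesity"].mean()
    parts = df.groupby("p1_bmi_category")["c2_obesity"].agg(["mean", "size"])
    weighted = float((parts["mean"] * parts["size"]).sum() / parts["size"].sum())
    assert whole == pytest.approx(weighted, abs=1e-12)
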