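import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pregformula as pf
from pregformula.derivations import (
    GrowthReference,
    UnderweightError,
    WeightChangeCategory,
    apply_eligibility,
    bmi_zscore,
    categorize_bmi,
    classify_child,
    compute_bmi,
    synthetic_normal_reference,
    weight_change_category,
)


@pytest.mark.parametrize(
    "weight, height, expected",
    [(60.0, 1.65, 22.04), (81.0, 1.70, 28.03), (70.0, 1.60, 27.34)],
)
def test_compute_bmi(weight, height, expected):
    assert compute_bmi(weight, height) == pytest.approx(expected, abs=0.005)


@pytest.mark.parametrize("weight, height", [(60.0, 0.0), (0.0, 1.6), (-5.0, 1.6)])
def test_compute_bmi_rejects_nonpositive(weight, height):
    with pytest.raises(ValueError):
        compute_bmi(weight, height)


@pytest.mark.parametrize(
    "bmi, category",
    [
        (18.5, "healthy"), (22.0, "healthy"), (24.99, "healthy"),
        (25.0, "overweight"), (29.99, "overweight"),
        (30.0, "obese"), (45.0, "obese"),
    ],
)
def test_categorize_bmi_half_open_boundaries(bmi, category):
    assert categorize_bmi(bmi) == category


def test_categorize_bmi_underweight_signals_upstream_bug():
    with pytest.raises(UnderweightError):
        categorize_bmi(18.4)


@given(st.floats(min_value=18.5, max_value=60.0, allow_nan=False))
@settings(derandomize=True, max_examples=200)
def test_categorize_bmi_partitions_domain(bmi):
    assert categorize_bmi(bmi) in ("healthy", "overweight", "obese")


@pytest.mark.parametrize(
    "bmi1, bmi2, expected",
    [
        (22.0, 22.5, WeightChangeCategory.stable),
        (27.0, 25.5, WeightChangeCategory.loss),
        (27.0, 26.0, WeightChangeCategory.loss),  # exactly -1: loss wins
        (22.0, 23.0, WeightChangeCategory.moderate_gain),  # exactly +1: gain wins
        (22.0, 24.99, WeightChangeCategory.moderate_gain),
        (30.0, 33.0, WeightChangeCategory.high_gain),
        (25.0, 24.1, WeightChangeCategory.stable),
    ],
)
def test_weight_change_categories(bmi1, bmi2, expected):
    assert weight_change_category(bmi1, bmi2) == expected


@given(
    st.floats(min_value=18.5, max_value=50.0, allow_nan=False),
    st.floats(min_value=18.5, max_value=50.0, allow_nan=False),
)
@settings(derandomize=True, max_examples=200)
def test_weight_change_partitions_domain(bmi1, bmi2):
    assert weight_change_category(bmi1, bmi2) in set(WeightChangeCategory)


def test_zscore_normal_reference_identity():
    ref = synthetic_normal_reference(mean=16.0, sd=1.3)
    assert bmi_zscore(16.0, "M", 4.5, ref) == pytest.approx(0.0)
    assert bmi_zscore(17.3, "F", 4.0, ref) == pytest.approx(1.0)


def test_zscore_lms_reduces_to_relative_deviation():
    ref = GrowthReference("lms", {("M", 4.0): (1.0, 16.0, 0.1)})
    assert bmi_zscore(17.6, "M", 4.0, ref) == pytest.approx(1.0)


def test_zscore_lms_small_L_matches_log_limit():
    ref_tiny = GrowthReference("lms", {("F", 4.0): (1e-12, 16.0, 0.1)})
    expected = np.log(17.0 / 16.0) / 0.1
    assert bmi_zscore(17.0, "F", 4.0, ref_tiny) == pytest.approx(expected, rel=1e-6)


def test_lms_reference_csv_round_trip(tmp_path):
    df = pd.DataFrame(
        {"sex": ["M", "M", "F"], "age_years": [4.0, 5.0, 4.5],
         "L": [-1.2, -1.3, -1.1], "M": [15.8, 15.6, 16.0], "S": [0.08, 0.09, 0.085]}
    )
    path = tmp_path / "lms.csv"
    df.to_csv(path, index=False)
    ref = GrowthReference.from_lms_csv(path)
    assert ref.kind == "lms"
    assert ref.lookup("M", 4.0) == (-1.2, 15.8, 0.08)
    # linear interpolation between tabulated ages
    L, M, S = ref.lookup("M", 4.5)
    assert M == pytest.approx((15.8 + 15.6) / 2)


def test_zscore_unknown_sex_raises():
    ref = synthetic_normal_reference()
    with pytest.raises(KeyError):
        bmi_zscore(16.0, "X", 4.5, ref)


@pytest.mark.parametrize(
    "z, expected",
    [(1.04, (True, False)), (1.65, (True, True)), (1.03, (False, False)), (-2.0, (False, False))],
)
def test_classify_child_thresholds(z, expected):
    assert classify_child(z) == expected


@given(st.floats(min_value=-5, max_value=5, allow_nan=False), st.floats(min_value=0, max_value=1))
@settings(derandomize=True, max_examples=100)
def test_classify_child_monotone_and_nested(z, bump):
    ow1, ob1 = classify_child(z)
    ow2, ob2 = classify_child(z + bump)
    assert ow2 >= ow1 and ob2 >= ob1  # monotone in z
    assert not (ob1 and not ow1)  # obesity implies overweight/obesity


def test_centile_thresholds_select_expected_tail_fractions():
    """With a normal reference, ~15% of children exceed the 85th-centile
    threshold and ~5% the 95th, up to the 2-dp rounding of +/-1.04, 1.65."""
    rng = np.random.default_rng(12345)
    z = rng.standard_normal(50_000)
    frac_ow = np.mean(z >= 1.04)
    frac_ob = np.mean(z >= 1.65)
    assert frac_ow == pytest.approx(0.15, abs=0.01)
    assert frac_ob == pytest.approx(0.05, abs=0.005)


def _mutate(df, i, **kv):
    for k, v in kv.items():
        df.loc[i, k] = v


def test_eligibility_rules_order_and_counts(cohort_small):
    df = cohort_small.df.copy()
    _mutate(df, 0, p1_gestation_at_ana_days=169.0)  # late first appointment
    _mutate(df, 1, p2_bmi=17.0)  # underweight
    _mutate(df, 2, p1_art=1)
    _mutate(df, 3, b1_gestational_age_days=150.0)
    _mutate(df, 4, c2_age_years=5.5)
    _mutate(df, 5, c2_bmi=np.nan)
    # violates both the appointment and underweight rules: counted once, first rule
    _mutate(df, 6, p1_gestation_at_ana_days=200.0, p1_bmi=17.0)
    table = pf.CohortTable(df)
    kept, counts = apply_eligibility(table)
    assert counts.counts == {
        "late_ana": 2, "underweight": 1, "art": 1,
        "gestation": 1, "child2_measurement": 2,
    }
    assert counts.n_retained == len(df) - 7
    assert len(kept) == counts.n_retained


def test_eligibility_is_idempotent(cohort_small):
    df = cohort_small.df.copy()
    df.loc[0, "p1_gestation_at_ana_days"] = 180.0
    once, c1 = apply_eligibility(pf.CohortTable(df))
    twice, c2 = apply_eligibility(once)
    pd.testing.assert_frame_equal(once.df, twice.df)
    assert sum(c2.counts.values()) == 0


def test_eligibility_clean_cohort_excludes_nothing(cohort_small):
    kept, counts = apply_eligibility(cohort_small)
    assert counts.n_retained == len(cohort_small)
    assert all(v == 0 for v in counts.counts.values())
    # the flowchart serialisation carries every rule
    import json

    payload = json.loads(counts.to_json())
    assert payload["n_input"] == len(cohort_small)
    assert len(payload["exclusions"]) == 5
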