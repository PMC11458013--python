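import numpy as np
import pytest

import pregformula as pf


@pytest.fixture(scope="session")
def params():
    """Calibrated default structural parameters (shared, treated read-only)."""
    return pf.default_params()


@pytest.fixture(scope="session")
def cohort_small(params):
    return pf.generate_cohort(params, 600, seed=42)


@pytest.fixture(scope="session")
def cohort_mid(params):
    return pf.generate_cohort(params, 5000, seed=7)


@pytest.fixture()
def light_config():
    """Small discrete model configuration for fast engine tests."""
    return pf.ModelConfig(
        predictor_terms=("bmi1_category", "smoking1"),
        covariate_order=("smoking2", "bmi2_category"),
        n_copies=5,
        seed=11,
    )


def enumerate_standardization(joint, overrides: dict) -> float:
    """Independent brute-force standardization by full enumeration.

    Written from the definition with explicit loops, separately from the
    vectorised implementation it checks: for every baseline stratum,
    accumulate the conditional probability of the non-intervened
    pregnancy-2 covariates, then weight the risk of each (baseline,
    intervened-completed pregnancy-2) cell.
    """
    import itertools

    b_names = list(joint.baseline_vars)
    p_names = list(joint.p2_vars)
    b_ranges = [range(len(v)) for v in joint.baseline_vars.values()]
    p_ranges = [range(len(v)) for v in joint.p2_vars.values()]
    over_idx = {
        name: list(joint.p2_vars[name]).index(value) for name, value in overrides.items()
    }
    total = 0.0
    for b in itertools.product(*b_ranges):
        pb = sum(float(joint.probs[b + p]) for p in itertools.product(*p_ranges))
        if pb == 0.0:
            continue
        free = [j for j, name in enumerate(p_names) if name not in over_idx]
        cond_free: dict = {}
        for p in itertools.product(*p_ranges):
            key = tuple(p[j] for j in free)
            cond_free[key] = cond_free.get(key, 0.0) + float(joint.probs[b + p]) / pb
        inner = 0.0
        for key, w in cond_free.items():
            full = [0] * len(p_names)
            for j, v in zip(free, key):
                full[j] = v
            for name, v in over_idx.items():
                full[p_names.index(name)] = v
            inner += w * float(joint.risks[b + tuple(full)])
        total += pb * inner
    return total
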