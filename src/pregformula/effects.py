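"""Population effect measures and nonparametric bootstrap intervals.

Every scenario is compared with the natural course of the same
population: the population risk ratio is the scenario prevalence divided
by the natural-course prevalence, and the population mean difference is
the prevalence difference in percentage points.  Confidence intervals are
percentile-bootstrap: mothers are resampled with replacement, the whole
fit-and-simulate procedure re-run per resample, and the 2.5th/97.5th
percentiles of each replicate quantity taken.  Ratios and differences are
computed within each replicate against that replicate's own natural
course so their dependence is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort_io import CohortTable
from .engine import OUTCOMES, ModelConfig, run_gformula
from .scenarios import DEFAULT_SCENARIOS

logger = logging.getLogger(__name__)

DEFAULT_BOOTSTRAP = 250


def risk_ratio(p_scenario: float, p_natural: float) -> float:
    """Population risk ratio: scenario prevalence over natural-course
    prevalence (scale-invariant in the shared units of its inputs)."""
    if p_natural <= 0:
        raise ZeroDivisionError("natural-course prevalence must be positive")
    return p_scenario / p_natural


def mean_difference(p_scenario: float, p_natural: float) -> float:
    """Population mean difference in percentage points, from proportions."""
    return (p_scenario - p_natural) * 100.0


def risk_reduction_percent(p_scenario: float, p_natural: float) -> float:
    """Percent reduction in risk relative to the natural course:
    100 * (1 - p_scenario / p_natural)."""
    return 100.0 * (1.0 - risk_ratio(p_scenario, p_natural))


@dataclass
class EffectTable:
    """Per-(stratum, scenario, outcome) prevalences, risk ratios and mean
    differences with percentile-bootstrap CIs; the shape of a standard
    intervention-comparison results table."""

    df: pd.DataFrame
    B: int = 0

    def row(self, stratum: str, scenario_id: int, outcome: str) -> pd.Series:
        m = (
            (self.df["stratum"] == stratum)
            & (self.df["scenario"] == scenario_id)
            & (self.df["outcome"] == outcome)
        )
        if not m.any():
            raise KeyError((stratum, scenario_id, outcome))
        return self.df.loc[m].iloc[0]


def bootstrap_seed(master_seed: int, replicate: int) -> int:
    """Documented counter for replicate engine seeds: reproducible and
    independent of how many replicates ran before."""
    return (master_seed * 1_000_003 + replicate + 1) % (2**31)


def bootstrap_cis(
    table: CohortTable,
    config: ModelConfig,
    scenarios=DEFAULT_SCENARIOS,
    B: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    stratum_label: str = "whole",
) -> EffectTable:
    """Point estimates from the original sample; percentile CIs from ``B``
    resamples of mothers with replacement.

    A replicate whose model fit fails is dropped with a logged count;
    more than 10% failures aborts.  For the natural course the risk ratio
    is exactly 1 and the mean difference exactly 0 in every replicate, so
    their intervals are degenerate and reported as such.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    point = run_gformula(table, config, scenarios, stratum=stratum_label)
    n = len(table.df)
    # resampling stream independent of the engine's simulation streams
    rng = np.random.default_rng(np.random.SeedSequence([seed, 424242]))
    reps: list[pd.DataFrame] = []
    failures = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sub = CohortTable(table.df.iloc[idx].reset_index(drop=True), table.provenance)
        cfg = replace(config, seed=bootstrap_seed(seed, b))
        try:
            est = run_gformula(sub, cfg, scenarios, stratum=stratum_label)
        except Exception as exc:
            failures += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
        reps.append(est.df.assign(replicate=b))
    if failures:
        logger.info("dropped %d failed bootstrap replicate(s) of %d", failures, B)
    if failures > 0.1 * B:
        raise RuntimeError(f"{failures} of {B} bootstrap replicates failed")
    rep_df = pd.concat(reps, ignore_index=True)

    rows = []
    for sc in scenarios:
        for outcome in OUTCOMES:
            p0_hat = point.get(0, outcome)
            p_hat = point.get(sc.id, outcome)
            sub = rep_df[(rep_df["scenario"] == sc.id) & (rep_df["outcome"] == outcome)]
            nat = rep_df[(rep_df["scenario"] == 0) & (rep_df["outcome"] == outcome)]
            merged = sub.merge(nat, on="replicate", suffixes=("", "_nat"))
            p = merged["prevalence"].to_numpy()
            p0 = merged["prevalence_nat"].to_numpy()
            if sc.id == 0:
                rr, rr_lo, rr_hi = 1.0, 1.0, 1.0
                md, md_lo, md_hi = 0.0, 0.0, 0.0
            else:
                md = mean_difference(p_hat, p0_hat)
                md_lo, md_hi = np.percentile((p - p0) * 100.0, [2.5, 97.5])
                if p0_hat <= 0:
                    # degenerate natural course: the ratio is undefined;
                    # flagged as NaN rather than aborting the whole table
                    logger.warning(
                        "natural-course prevalence is zero for outcome %r; "
                        "risk ratios reported as NaN", outcome)
                    rr = rr_lo = rr_hi = float("nan")
                else:
                    rr = risk_ratio(p_hat, p0_hat)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        ratios = np.where(p0 > 0, p / np.where(p0 > 0, p0, 1.0), np.nan)
                    if np.isnan(ratios).all():
                        rr_lo = rr_hi = float("nan")
                    else:
                        rr_lo, rr_hi = np.nanpercentile(ratios, [2.5, 97.5])
            lo, hi = np.percentile(p, [2.5, 97.5])
            rows.append(
                {
                    "stratum": stratum_label,
                    "scenario": sc.id,
                    "description": sc.description,
                    "outcome": outcome,
                    "prevalence_pct": p_hat * 100.0,
                    "prevalence_lo": lo * 100.0,
                    "prevalence_hi": hi * 100.0,
                    "risk_ratio": rr,
                    "rr_lo": rr_lo,
                    "rr_hi": rr_hi,
                    "mean_difference": md,
                    "md_lo": md_lo,
                    "md_hi": md_hi,
                    "B": len(merged),
                }
            )
    return EffectTable(pd.DataFrame(rows), B=B)
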