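"""Monte-Carlo parametric g-formula engine.

Fits causally ordered parametric models for the pregnancy-2 covariates
(smoking, BMI category, systolic blood pressure by default) and for the
child outcome, then standardizes: every mother is replicated ``n_copies``
times, her baseline and pregnancy-1 covariates held at their observed
values, her pregnancy-2 covariates drawn sequentially from the fitted
models, any intervened covariate overwritten per the scenario, and the
fitted outcome probability averaged over all copies.  Averaging predicted
probabilities rather than sampled outcomes removes one layer of
Monte-Carlo noise.

Each scenario is simulated from an identically seeded random stream
(common random numbers), so a no-op intervention reproduces the natural
course exactly and scenario contrasts are not inflated by simulation
noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special
from sklearn.linear_model import LogisticRegression

from .cohort_io import BMI_CATEGORIES, EDUCATIONS, ETHNICITIES, CohortTable
from .scenarios import DEFAULT_SCENARIOS, ScenarioSpec

logger = logging.getLogger(__name__)

OUTCOMES = ("overweight_obesity", "obesity")
_OUTCOME_COLS = {"overweight_obesity": "c2_overweight_obesity", "obesity": "c2_obesity"}

#: term name -> (cohort column, kind[, levels])
TERMS: dict[str, tuple] = {
    "age_p1": ("age_p1", "continuous"),
    "ethnicity": ("ethnicity", "categorical", ETHNICITIES),
    "education": ("education", "categorical", EDUCATIONS),
    "employed": ("employed", "binary"),
    "bmi1_category": ("p1_bmi_category", "categorical", BMI_CATEGORIES),
    "smoking1": ("p1_smoking", "binary"),
    "sbp1": ("p1_sbp", "continuous"),
    "interval_months": ("interpregnancy_interval_months", "continuous"),
    "smoking2": ("p2_smoking", "binary"),
    "bmi2_category": ("p2_bmi_category", "categorical", BMI_CATEGORIES),
    "sbp2": ("p2_sbp", "continuous"),
}

#: family per simulated pregnancy-2 covariate
COVARIATE_FAMILY = {
    "smoking2": "binary",
    "bmi2_category": "multinomial",
    "sbp2": "gaussian",
}

DEFAULT_PREDICTORS = (
    "ethnicity",
    "education",
    "employed",
    "age_p1",
    "bmi1_category",
    "smoking1",
    "sbp1",
)


class FittingError(RuntimeError):
    """A model could not be fitted; carries the model name."""


class ConfigError(ValueError):
    """The model configuration is internally inconsistent."""


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of the causally ordered models and the simulation.

    ``covariate_order`` lists the pregnancy-2 covariates in the causal
    order in which they are simulated; every model may only condition on
    baseline/pregnancy-1 terms and covariates earlier in this order.
    ``saturated`` replaces each model's additive terms by a single
    fully-interacted cell indicator (used for exact-standardization
    checks on discrete data).  Birth-2 variables are never predictors in
    the outcome model: they are descendants of the intervened exposures.
    """

    covariate_order: tuple[str, ...] = ("smoking2", "bmi2_category", "sbp2")
    predictor_terms: tuple[str, ...] = DEFAULT_PREDICTORS
    outcome_terms: tuple[str, ...] | None = None
    n_copies: int = 10
    seed: int = 0
    saturated: bool = False
    min_stratum_n: int = 50

    def __post_init__(self) -> None:
        if len(set(self.covariate_order)) != len(self.covariate_order):
            raise ConfigError("covariate_order must list each variable once")
        for v in self.covariate_order:
            if v not in COVARIATE_FAMILY:
                raise ConfigError(f"unknown simulated covariate {v!r}")
        for t in self.predictor_terms:
            if t not in TERMS:
                raise ConfigError(f"unknown predictor term {t!r}")
        if self.outcome_terms is not None:
            for t in self.outcome_terms:
                if t not in TERMS:
                    raise ConfigError(f"unknown outcome term {t!r}")
                if t in COVARIATE_FAMILY and t not in self.covariate_order:
                    raise ConfigError(
                        f"outcome term {t!r} is a simulated covariate missing "
                        "from covariate_order"
                    )
        if self.n_copies < 1:
            raise ConfigError("n_copies must be >= 1")

    def terms_for_covariate(self, cov: str) -> tuple[str, ...]:
        i = self.covariate_order.index(cov)
        return self.predictor_terms + self.covariate_order[:i]

    def terms_for_outcome(self) -> tuple[str, ...]:
        if self.outcome_terms is not None:
            return self.outcome_terms
        return self.predictor_terms + self.covariate_order


# ---------------------------------------------------------------------------
# Design-matrix encoding


class _Encoder:
    """Fixed-term design-matrix builder, consistent between fit and simulate.

    Continuous terms are standardized with training mean/sd; categoricals
    are one-hot with the first level dropped.  Under ``saturated`` the
    terms collapse to a single cross-classified cell indicator whose levels
    are the cells observed at fit time (unseen cells at prediction map to
    the reference cell).

    ``transform`` accepts an optional per-term block cache so that the
    encodings of held (non-simulated) covariates are computed once per
    simulation run rather than once per scenario and model.
    """

    def __init__(self, terms: tuple[str, ...], saturated: bool = False):
        self.terms = terms
        self.saturated = saturated
        self.stats: dict[str, tuple[float, float]] = {}
        self.cells: list[str] | None = None

    @staticmethod
    def _raw(data: dict, term: str) -> np.ndarray:
        if term not in data:
            raise FittingError(f"term {term!r} has no backing data column")
        return np.asarray(data[term])

    def _level_index(self, t: str, x: np.ndarray) -> np.ndarray:
        spec = TERMS[t]
        if spec[1] == "binary":
            return np.asarray(x).astype(np.int64)
        if spec[1] == "categorical":
            idx = np.zeros(len(x), dtype=np.int64)
            for j, lv in enumerate(spec[2][1:], start=1):
                idx[np.asarray(x) == lv] = j
            return idx
        raise FittingError(f"saturated models require discrete terms; {t!r} is continuous")

    def fit(self, data: dict) -> "_Encoder":
        if self.saturated:
            dims = []
            for t in self.terms:
                spec = TERMS[t]
                if spec[1] == "binary":
                    dims.append(2)
                elif spec[1] == "categorical":
                    dims.append(len(spec[2]))
                else:
                    raise FittingError(
                        f"saturated models require discrete terms; {t!r} is continuous")
            self.dims = dims
            self.n_cells = int(np.prod(dims))
            return self
        for t in self.terms:
            if TERMS[t][1] == "continuous":
                x = self._raw(data, t).astype(float)
                sd = float(np.std(x))
                self.stats[t] = (float(np.mean(x)), sd if sd > 0 else 1.0)
        return self

    def _encode_term(self, t: str, x: np.ndarray) -> np.ndarray:
        spec = TERMS[t]
        if spec[1] == "continuous":
            mean, sd = self.stats[t]
            return ((x.astype(float) - mean) / sd)[:, None]
        if spec[1] == "binary":
            return x.astype(float)[:, None]
        levels = spec[2]
        return np.stack([(x == lv).astype(float) for lv in levels[1:]], axis=1)

    def cell_codes(self, data: dict) -> np.ndarray:
        """Mixed-radix integer cell index over the full level product."""
        code = self._level_index(self.terms[0], self._raw(data, self.terms[0]))
        for t, dim in zip(self.terms[1:], self.dims[1:]):
            code = code * dim + self._level_index(t, self._raw(data, t))
        return code

    def _held_prefix(self) -> tuple[str, ...]:
        # leading run of non-simulated terms; their joint encoding is
        # constant within a run and cacheable across scenarios and models
        out = []
        for t in self.terms:
            if t in COVARIATE_FAMILY:
                break
            out.append(t)
        return tuple(out)

    def transform(self, data: dict, block_cache: dict | None = None) -> np.ndarray:
        n = len(self._raw(data, self.terms[0]))
        if self.saturated:
            raise FittingError("saturated encoders are indexed via cell_codes")
        prefix = self._held_prefix() if block_cache is not None else ()
        blocks = []
        if prefix:
            blocks.append(self._held_block(data, block_cache))
        for t in self.terms[len(prefix):]:
            blocks.append(self._encode_term(t, self._raw(data, t)))
        if not blocks:
            return np.zeros((n, 0))
        return blocks[0] if len(blocks) == 1 else np.concatenate(blocks, axis=1)

    def _held_block(self, data: dict, block_cache: dict) -> np.ndarray:
        prefix = self._held_prefix()
        key = ("prefix", prefix)
        if key not in block_cache:
            block_cache[key] = np.concatenate(
                [self._encode_term(t, self._raw(data, t)) for t in prefix], axis=1
            )
        return block_cache[key]

    def split_design(self, data: dict, block_cache: dict) -> tuple[np.ndarray | None, np.ndarray | None]:
        """(held, simulated) design blocks for the linear fast path; the
        held block is cached across scenarios and models."""
        prefix = self._held_prefix()
        Xh = self._held_block(data, block_cache) if prefix else None
        sim_terms = self.terms[len(prefix):]
        if sim_terms:
            Xs = np.concatenate(
                [self._encode_term(t, self._raw(data, t)) for t in sim_terms], axis=1
            )
        else:
            Xs = None
        return Xh, Xs


# ---------------------------------------------------------------------------
# Model families


class _ConstantBinary:
    def __init__(self, p: float):
        self.p = float(p)

    def predict_p(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self.p)

    def predict_split(self, Xh, Xs, cache, tag, n: int) -> np.ndarray:
        return np.full(n, self.p)


def _make_logit(multinomial: bool = False) -> LogisticRegression:
    # near-unpenalized logistic fits (the weak ridge only stabilises
    # near-separated sparse categories)
    if multinomial:
        return LogisticRegression(C=1e4, solver="newton-cg", max_iter=50, tol=1e-5)
    return LogisticRegression(C=1e4, solver="lbfgs", max_iter=150, tol=1e-5)


class _Binary:
    def __init__(self, name: str):
        self.name = name
        self.clf = _make_logit()

    def fit(self, X: np.ndarray, y: np.ndarray):
        try:
            with warnings.catch_warnings():
                # iteration cap under near-separation is deliberate
                warnings.simplefilter("ignore")
                self.clf.fit(X, y)
        except Exception as exc:
            raise FittingError(f"model {self.name!r} failed to fit: {exc}") from exc
        return self

    def predict_p(self, X: np.ndarray) -> np.ndarray:
        # direct evaluation; skips sklearn's per-call input validation
        f = X @ self.clf.coef_[0] + self.clf.intercept_[0]
        p = special.expit(f)
        return p if self.clf.classes_[1] == 1 else 1.0 - p

    def predict_split(self, Xh, Xs, cache, tag, n: int) -> np.ndarray:
        f = _linear_f(self.clf.coef_.T, self.clf.intercept_, Xh, Xs, cache, tag, n)
        p = special.expit(f[:, 0])
        return p if self.clf.classes_[1] == 1 else 1.0 - p


class _Multinomial:
    def __init__(self, name: str, levels: tuple[str, ...]):
        self.name = name
        self.levels = levels
        self.clf = _make_logit(multinomial=True)

    def fit(self, X: np.ndarray, y: np.ndarray):
        if len(set(y)) == 1:
            self.constant = str(next(iter(set(y))))
            return self
        self.constant = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.clf.fit(X, y)
        except Exception as exc:
            raise FittingError(f"model {self.name!r} failed to fit: {exc}") from exc
        return self

    def _probs_from_f(self, f: np.ndarray) -> np.ndarray:
        out = np.zeros((f.shape[0], len(self.levels)))
        if f.shape[1] == 1:  # two observed classes: binomial parameterisation
            p1 = special.expit(f[:, 0])
            probs = np.column_stack([1.0 - p1, p1])
        else:
            f = f - f.max(axis=1, keepdims=True)
            np.exp(f, out=f)
            probs = f / f.sum(axis=1, keepdims=True)
        for j, cls in enumerate(self.clf.classes_):
            out[:, self.levels.index(str(cls))] = probs[:, j]
        return out

    def _constant_probs(self, n: int) -> np.ndarray:
        out = np.zeros((n, len(self.levels)))
        out[:, self.levels.index(self.constant)] = 1.0
        return out

    def predict_p(self, X: np.ndarray) -> np.ndarray:
        """Probabilities over the full level set, columns in level order."""
        if self.constant is not None:
            return self._constant_probs(X.shape[0])
        return self._probs_from_f(X @ self.clf.coef_.T + self.clf.intercept_)

    def predict_split(self, Xh, Xs, cache, tag, n: int) -> np.ndarray:
        if self.constant is not None:
            return self._constant_probs(n)
        f = _linear_f(self.clf.coef_.T, self.clf.intercept_, Xh, Xs, cache, tag, n)
        return self._probs_from_f(f)


class _SaturatedBinary:
    """Empirical cell proportions: the MLE of a saturated logistic model.

    Unseen cells at prediction fall back to the marginal proportion."""

    def __init__(self, name: str):
        self.name = name

    def fit(self, codes: np.ndarray, y: np.ndarray, n_cells: int):
        counts = np.bincount(codes, minlength=n_cells).astype(float)
        sums = np.bincount(codes, weights=y, minlength=n_cells)
        self.fallback = float(np.mean(y))
        with np.errstate(invalid="ignore"):
            self.p_cell = np.where(counts > 0, sums / np.maximum(counts, 1), self.fallback)
        return self

    def predict_codes(self, codes: np.ndarray) -> np.ndarray:
        return np.where(codes >= 0, self.p_cell[np.maximum(codes, 0)], self.fallback)


class _SaturatedMultinomial:
    """Per-cell level proportions: the MLE of a saturated multinomial."""

    def __init__(self, name: str, levels: tuple[str, ...]):
        self.name = name
        self.levels = levels

    def fit(self, codes: np.ndarray, y: np.ndarray, n_cells: int):
        k = len(self.levels)
        counts = np.zeros((n_cells, k))
        for j, lv in enumerate(self.levels):
            counts[:, j] = np.bincount(codes[y == lv], minlength=n_cells)
        total = counts.sum(axis=1, keepdims=True)
        marginal = counts.sum(axis=0)
        self.fallback = marginal / marginal.sum()
        with np.errstate(invalid="ignore"):
            self.p_cell = np.where(total > 0, counts / np.maximum(total, 1), self.fallback)
        return self

    def predict_codes(self, codes: np.ndarray) -> np.ndarray:
        out = self.p_cell[np.maximum(codes, 0)]
        out[codes < 0] = self.fallback
        return out


class _SaturatedGaussian:
    """Per-cell means with a pooled residual standard deviation."""

    def __init__(self, name: str):
        self.name = name

    def fit(self, codes: np.ndarray, y: np.ndarray, n_cells: int):
        counts = np.bincount(codes, minlength=n_cells).astype(float)
        sums = np.bincount(codes, weights=y, minlength=n_cells)
        self.fallback = float(np.mean(y))
        self.mean_cell = np.where(counts > 0, sums / np.maximum(counts, 1), self.fallback)
        resid = y - self.mean_cell[codes]
        self.resid_sd = float(np.sqrt(np.mean(resid**2))) or 1e-12
        return self

    def predict_codes(self, codes: np.ndarray) -> np.ndarray:
        return np.where(codes >= 0, self.mean_cell[np.maximum(codes, 0)], self.fallback)


def _linear_f(
    coef2d: np.ndarray,
    intercept: np.ndarray,
    Xh: np.ndarray | None,
    Xs: np.ndarray | None,
    cache: dict,
    tag,
    n: int,
) -> np.ndarray:
    """(n, m) linear predictor from split design blocks; the held-block
    contribution Xh @ coef_held is computed once per run and cached."""
    kh = 0 if Xh is None else Xh.shape[1]
    if Xh is not None:
        key = ("heldf", tag)
        if key not in cache:
            cache[key] = Xh @ coef2d[:kh]
        f = cache[key] + intercept
    else:
        f = np.broadcast_to(intercept, (n, coef2d.shape[1])).copy()
    if Xs is not None and Xs.shape[1]:
        f = f + Xs @ coef2d[kh:]
    return f


class _Gaussian:
    def __init__(self, name: str):
        self.name = name

    def fit(self, X: np.ndarray, y: np.ndarray):
        A = np.column_stack([np.ones(len(y)), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.coef = coef
        resid = y - A @ coef
        dof = max(len(y) - A.shape[1], 1)
        self.resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
        if self.resid_sd <= 0:
            self.resid_sd = 1e-12
        return self

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(X.shape[0]), X]) @ self.coef

    def predict_split(self, Xh, Xs, cache, tag, n: int) -> np.ndarray:
        f = _linear_f(self.coef[1:, None], self.coef[:1], Xh, Xs, cache, tag, n)
        return f[:, 0]


@dataclass
class FittedModels:
    """The causally ordered fitted models plus their encoders."""

    config: ModelConfig
    covariate_models: dict = field(default_factory=dict)
    covariate_encoders: dict = field(default_factory=dict)
    outcome_models: dict = field(default_factory=dict)
    outcome_encoder: _Encoder | None = None
    n_fit: int = 0
    n_dropped_missing: int = 0


# ---------------------------------------------------------------------------


def _required_columns(config: ModelConfig) -> list[str]:
    cols = [TERMS[t][0] for t in config.predictor_terms]
    cols += [TERMS[v][0] for v in config.covariate_order]
    if config.outcome_terms:
        cols += [TERMS[t][0] for t in config.outcome_terms]
    return sorted(set(cols))


def complete_cases(table: CohortTable, config: ModelConfig) -> tuple[pd.DataFrame, int]:
    """Rows complete on every modelled column; the dropped count is logged."""
    cols = _required_columns(config)
    mask = table.df[cols].notna().all(axis=1)
    dropped = int((~mask).sum())
    if dropped == 0:
        return table.df, 0
    logger.info("complete-case analysis: dropped %d row(s) with missing values", dropped)
    return table.df.loc[mask].reset_index(drop=True), dropped


def _term_data(df: pd.DataFrame, terms) -> dict[str, np.ndarray]:
    return {t: df[TERMS[t][0]].to_numpy() for t in terms}


def fit_models(table: CohortTable, config: ModelConfig) -> FittedModels:
    """Fit one model per simulated pregnancy-2 covariate, in causal order,
    plus a logistic outcome model per outcome definition.

    Each covariate is regressed on the baseline/pregnancy-1 predictor
    terms and all covariates earlier in ``covariate_order``; the outcome
    on predictors plus every simulated covariate.  A constant outcome
    yields a degenerate model predicting that constant probability.
    """
    df, dropped = complete_cases(table, config)
    return _fit_on_frame(df, config, dropped)


def _fit_on_frame(df: pd.DataFrame, config: ModelConfig, dropped: int = 0) -> FittedModels:
    if len(df) == 0:
        raise FittingError("no complete-case rows to fit on")
    fitted = FittedModels(config=config, n_fit=len(df), n_dropped_missing=dropped)
    for cov in config.covariate_order:
        terms = config.terms_for_covariate(cov)
        enc = _Encoder(terms, config.saturated).fit(_term_data(df, terms))
        col = TERMS[cov][0]
        family = COVARIATE_FAMILY[cov]
        if config.saturated:
            codes = enc.cell_codes(_term_data(df, terms))
            cls = {"binary": _SaturatedBinary, "gaussian": _SaturatedGaussian}.get(family)
            if cls is not None:
                model = cls(cov).fit(codes, df[col].to_numpy().astype(float), enc.n_cells)
            else:
                model = _SaturatedMultinomial(cov, TERMS[cov][2]).fit(
                    codes, df[col].to_numpy().astype(str), enc.n_cells)
        elif family == "binary":
            X = enc.transform(_term_data(df, terms))
            y = df[col].to_numpy().astype(int)
            model = (_ConstantBinary(y.mean()) if len(set(y)) == 1
                     else _Binary(cov).fit(X, y))
        elif family == "multinomial":
            X = enc.transform(_term_data(df, terms))
            model = _Multinomial(cov, TERMS[cov][2]).fit(X, df[col].to_numpy().astype(str))
        else:
            X = enc.transform(_term_data(df, terms))
            model = _Gaussian(cov).fit(X, df[col].to_numpy().astype(float))
        fitted.covariate_models[cov] = model
        fitted.covariate_encoders[cov] = enc
    out_terms = config.terms_for_outcome()
    enc = _Encoder(out_terms, config.saturated).fit(_term_data(df, out_terms))
    fitted.outcome_encoder = enc
    if not config.saturated:
        X = enc.transform(_term_data(df, out_terms))
    else:
        codes = enc.cell_codes(_term_data(df, out_terms))
    for outcome in OUTCOMES:
        y = df[_OUTCOME_COLS[outcome]].to_numpy().astype(int)
        if config.saturated:
            fitted.outcome_models[outcome] = _SaturatedBinary(
                f"outcome:{outcome}").fit(codes, y.astype(float), enc.n_cells)
        elif len(set(y)) == 1:
            fitted.outcome_models[outcome] = _ConstantBinary(y.mean())
        else:
            fitted.outcome_models[outcome] = _Binary(f"outcome:{outcome}").fit(X, y)
    return fitted


def _simulate_covariates(
    models: FittedModels,
    df: pd.DataFrame,
    scenario: ScenarioSpec,
    config: ModelConfig,
    block_cache: dict | None = None,
) -> dict[str, np.ndarray]:
    """Replicate subjects, draw pregnancy-2 covariates sequentially, apply
    the scenario's overrides.  The random stream is re-seeded identically
    per scenario and the number of draws is scenario-independent, so all
    scenarios share common random numbers."""
    if scenario.bmi_intervention is not None and "bmi2_category" not in config.covariate_order:
        raise ConfigError("scenario intervenes on bmi2_category, absent from covariate_order")
    if scenario.smoking_cessation and "smoking2" not in config.covariate_order:
        raise ConfigError("scenario intervenes on smoking2, absent from covariate_order")
    rng = np.random.default_rng(config.seed)
    rep = np.repeat(np.arange(len(df)), config.n_copies)
    held = set(config.predictor_terms) | {
        t for t in config.terms_for_outcome() if t not in COVARIATE_FAMILY
    }
    data = {t: df[TERMS[t][0]].to_numpy()[rep] for t in held}
    N = len(rep)
    for cov in config.covariate_order:
        enc = models.covariate_encoders[cov]
        model = models.covariate_models[cov]
        family = COVARIATE_FAMILY[cov]
        sub = {t: data[t] for t in enc.terms}
        if enc.saturated:
            codes = enc.cell_codes(sub)
            predict = lambda: model.predict_codes(codes)
        elif block_cache is not None:
            Xh, Xs = enc.split_design(sub, block_cache)
            predict = lambda: model.predict_split(Xh, Xs, block_cache, cov, N)
        else:
            X = enc.transform(sub, block_cache)
            predict = lambda: (model.predict_mean(X) if family == "gaussian"
                               else model.predict_p(X))
        if family == "binary":
            p = predict()
            val = (rng.random(N) < p).astype(int)
            if cov == "smoking2" and scenario.smoking_cessation:
                val = np.zeros(N, dtype=int)
        elif family == "multinomial":
            probs = predict()
            cum = np.cumsum(probs, axis=1)
            idx = np.minimum((rng.random(N)[:, None] > cum).sum(axis=1), probs.shape[1] - 1)
            val = np.asarray(TERMS[cov][2], dtype=object)[idx]
            if cov == "bmi2_category" and scenario.bmi_intervention is not None:
                val = np.full(N, scenario.bmi_intervention, dtype=object)
        else:
            mu = predict()
            val = mu + model.resid_sd * rng.standard_normal(N)
        data[cov] = val
    return data


def _outcome_prevalences(
    models: FittedModels, data: dict, block_cache: dict | None = None
) -> dict[str, float]:
    enc = models.outcome_encoder
    sub = {t: data[t] for t in enc.terms}
    if enc.saturated:
        codes = enc.cell_codes(sub)
        return {
            outcome: float(np.mean(models.outcome_models[outcome].predict_codes(codes)))
            for outcome in OUTCOMES
        }
    if block_cache is not None:
        Xh, Xs = enc.split_design(sub, block_cache)
        n = len(next(iter(sub.values())))
        return {
            outcome: float(np.mean(
                models.outcome_models[outcome].predict_split(
                    Xh, Xs, block_cache, f"outcome:{outcome}", n)
            ))
            for outcome in OUTCOMES
        }
    X = enc.transform(sub, block_cache)
    return {
        outcome: float(np.mean(models.outcome_models[outcome].predict_p(X)))
        for outcome in OUTCOMES
    }


def simulate_scenario(
    models: FittedModels,
    table: CohortTable,
    scenario: ScenarioSpec,
    config: ModelConfig,
    outcome: str = "overweight_obesity",
) -> float:
    """Mean fitted outcome probability over all copies of all subjects
    under one scenario."""
    df, _ = complete_cases(table, config)
    data = _simulate_covariates(models, df, scenario, config)
    return _outcome_prevalences(models, data)[outcome]


@dataclass
class EstimateSet:
    """Per-(scenario, outcome) g-formula prevalence estimates."""

    df: pd.DataFrame  # columns: scenario, outcome, prevalence
    stratum: str = "whole"
    n: int = 0
    n_copies: int = 0
    seed: int = 0

    def get(self, scenario_id: int, outcome: str) -> float:
        m = (self.df["scenario"] == scenario_id) & (self.df["outcome"] == outcome)
        if not m.any():
            raise KeyError((scenario_id, outcome))
        return float(self.df.loc[m, "prevalence"].iloc[0])


def run_gformula(
    table: CohortTable,
    config: ModelConfig,
    scenarios=DEFAULT_SCENARIOS,
    stratum: str = "whole",
) -> EstimateSet:
    """Fit once, then simulate every scenario for both outcome definitions.

    Deterministic given (table, config, scenarios): each scenario draws
    from an identically seeded stream.
    """
    ids = [s.id for s in scenarios]
    if 0 not in ids:
        raise ConfigError("scenarios must include the natural course (id 0)")
    df, dropped = complete_cases(table, config)
    models = _fit_on_frame(df, config, dropped)
    rows = []
    block_cache: dict = {}  # held-term encodings shared across scenarios
    for sc in scenarios:
        data = _simulate_covariates(models, df, sc, config, block_cache)
        prevs = _outcome_prevalences(models, data, block_cache)
        for outcome in OUTCOMES:
            rows.append({"scenario": sc.id, "outcome": outcome, "prevalence": prevs[outcome]})
    return EstimateSet(
        pd.DataFrame(rows), stratum=stratum, n=len(df), n_copies=config.n_copies,
        seed=config.seed,
    )


def run_stratified(
    table: CohortTable,
    config: ModelConfig,
    scenarios=DEFAULT_SCENARIOS,
    stratifier: str = "p1_bmi_category",
) -> dict[str, EstimateSet | None]:
    """Re-run the full fit-and-simulate procedure independently within
    each first-pregnancy BMI stratum (stratum-specific models).

    Strata absent from the data or below ``config.min_stratum_n`` map to
    ``None`` with a warning rather than failing silently.
    """
    out: dict[str, EstimateSet | None] = {}
    for label in BMI_CATEGORIES:
        sub = table.df[table.df[stratifier] == label]
        if len(sub) == 0:
            warnings.warn(f"stratum {label!r} absent from data; skipped")
            out[label] = None
            continue
        if len(sub) < config.min_stratum_n:
            warnings.warn(
                f"stratum {label!r} has n={len(sub)} < {config.min_stratum_n}; skipped"
            )
            out[label] = None
            continue
        out[label] = run_gformula(
            CohortTable(sub.reset_index(drop=True), table.provenance),
            config, scenarios, stratum=label,
        )
    return out
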