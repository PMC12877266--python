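"""Synthetic cohort generator with known causal structure.

Generates tabular cohorts that mimic the structure of a population-based
nutritional-epidemiology study: categorical baseline covariates L, food-group
intakes A in g/d that depend on L (confounding), a binary cognitive outcome Y
generated from a known structural model, and loss to follow-up C that is
missing-at-random given L.  Because the structural coefficients are known,
the true average causal effect of any intake shift can be computed exactly
(identity link) or by direct evaluation of the true model (logit link), which
makes every downstream estimation stage testable without restricted data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "IntakeModel",
    "OutcomeModel",
    "CensoringModel",
    "SimulationTruth",
    "generate_truth",
    "generate_cohort",
    "true_ace",
    "SCENARIOS",
    "FOOD_GROUPS",
    "NON_DAIRY_GROUPS",
    "DAIRY_ITEMS",
]

# Non-dairy food groups forming the rest of the diet ("all-component" set).
NON_DAIRY_GROUPS = (
    "vegetables",
    "fruits",
    "fish",
    "meat",
    "eggs",
    "grains",
    "alcohol",
    "sugary_processed",
    "high_fat_foods",
)
FOOD_GROUPS = ("total_dairy",) + NON_DAIRY_GROUPS

# Item-level dairy columns; per-row shares of total dairy are drawn from a
# Dirichlet so item sums reproduce the generated group total exactly.
DAIRY_ITEMS = ("milk", "yogurt", "cheese", "cream", "butter", "dairy_dessert")
_DAIRY_SHARE_CONC = np.array([9.0, 4.0, 3.0, 1.0, 1.0, 2.0])

_PROB_TOL = 1e-12


@dataclass
class IntakeModel:
    """Gamma intake model: mean = exp(intercept + sum coef * dummy), fixed shape.

    The log link keeps conditional means positive; the gamma family gives the
    nonnegative right-skewed shape typical of FFQ-derived g/d intakes.
    """

    shape: float
    log_mean_intercept: float
    log_mean_coefs: dict[str, float] = field(default_factory=dict)

    def mean(self, dummies: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(dummies), self.log_mean_intercept)
        for key, coef in self.log_mean_coefs.items():
            if key not in dummies.columns:
                raise KeyError(f"intake model references unknown covariate level {key!r}")
            eta = eta + coef * dummies[key].to_numpy(float)
        return np.exp(eta)


@dataclass
class OutcomeModel:
    """Structural outcome model: P(Y=1) = g(intercept + food terms + covariate terms).

    Food coefficients are per 100 g/d.  link is "identity" (linear probability,
    closed-form true effects) or "logit".
    """

    link: str = "identity"
    intercept: float = 0.25
    food_coefs: dict[str, float] = field(default_factory=dict)
    covariate_coefs: dict[str, float] = field(default_factory=dict)

    def linear_predictor(self, intakes: pd.DataFrame, dummies: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(intakes), float(self.intercept))
        for group, coef in self.food_coefs.items():
            eta = eta + coef * intakes[group].to_numpy(float) / 100.0
        for key, coef in self.covariate_coefs.items():
            eta = eta + coef * dummies[key].to_numpy(float)
        return eta

    def prob(self, intakes: pd.DataFrame, dummies: pd.DataFrame) -> np.ndarray:
        eta = self.linear_predictor(intakes, dummies)
        if self.link == "identity":
            return eta
        if self.link == "logit":
            return expit(eta)
        raise ValueError(f"unknown link {self.link!r}")


@dataclass
class CensoringModel:
    """Logistic model for remaining under follow-up: P(C=1 | L)."""

    intercept: float = 10.0  # effectively no dropout unless overridden
    coefs: dict[str, float] = field(default_factory=dict)

    def prob_followed(self, dummies: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(dummies), float(self.intercept))
        for key, coef in self.coefs.items():
            eta = eta + coef * dummies[key].to_numpy(float)
        return expit(eta)


@dataclass
class SimulationTruth:
    """Complete generating mechanism for one synthetic-cohort scenario."""

    confounder_margins: dict[str, dict[str, float]]
    intake_model: dict[str, IntakeModel]
    outcome_model: OutcomeModel
    censoring_model: CensoringModel
    n: int = 5000
    seed: int = 0
    waves: int = 1
    scenario: str = "custom"

    def __post_init__(self) -> None:
        for cov, margin in self.confounder_margins.items():
            total = sum(margin.values())
            if abs(total - 1.0) > _PROB_TOL:
                raise ValueError(
                    f"category probabilities for {cov!r} sum to {total!r}, not 1"
                )
            if any(p < 0 for p in margin.values()):
                raise ValueError(f"negative category probability for {cov!r}")
        missing = [g for g in FOOD_GROUPS if g not in self.intake_model]
        if missing:
            raise ValueError(f"intake model missing food groups: {missing}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        self._check_outcome_bounds()

    def _check_outcome_bounds(self) -> None:
        """Reject identity-link outcome models that can leave [0,1].

        The bound is evaluated at the extremes of the effective intake support
        (the 1-1e-8 gamma quantile per food group at its worst covariate
        pattern) so the generator never needs to clamp or re-draw.  Covariate
        levels of the same covariate are mutually exclusive, so extremes are
        taken per covariate, not summed over levels.
        """
        if self.outcome_model.link != "identity":
            return
        from scipy.stats import gamma as gamma_dist

        def per_covariate_extreme(coefs: dict, side: str) -> float:
            by_cov: dict[str, list[float]] = {}
            for key, coef in coefs.items():
                by_cov.setdefault(key.split("=", 1)[0], []).append(coef)
            total = 0.0
            for values in by_cov.values():
                # the reference level contributes 0
                if side == "hi":
                    total += max(0.0, max(values))
                else:
                    total += min(0.0, min(values))
            return total

        lo = float(self.outcome_model.intercept)
        hi = float(self.outcome_model.intercept)
        lo += per_covariate_extreme(self.outcome_model.covariate_coefs, "lo")
        hi += per_covariate_extreme(self.outcome_model.covariate_coefs, "hi")
        for group, coef in self.outcome_model.food_coefs.items():
            if coef == 0.0:
                continue
            model = self.intake_model[group]
            log_mean = model.log_mean_intercept + per_covariate_extreme(
                model.log_mean_coefs, "hi"
            )
            q_hi = gamma_dist.ppf(1 - 1e-8, model.shape, scale=np.exp(log_mean) / model.shape)
            term = coef * q_hi / 100.0
            lo += min(0.0, term)
            hi += max(0.0, term)
        if lo < 0.0 or hi > 1.0:
            raise ValueError(
                "identity-link outcome model can produce probabilities outside "
                f"[0,1] over the intake support (range [{lo:.3f}, {hi:.3f}]); "
                "shrink the coefficients"
            )

    # --- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "SimulationTruth":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        payload["intake_model"] = {
            g: IntakeModel(**m) for g, m in payload["intake_model"].items()
        }
        payload["outcome_model"] = OutcomeModel(**payload["outcome_model"])
        payload["censoring_model"] = CensoringModel(**payload["censoring_model"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------

def _uniform_margins() -> dict[str, dict[str, float]]:
    return {
        "age_group": {"<70": 0.61, "70-74": 0.22, ">74": 0.17},
        "sex": {"female": 0.58, "male": 0.42},
        "education": {"elementary": 0.68, "high_school": 0.16, "superior": 0.16},
        "occupation": {"high": 0.05, "middle": 0.11, "low": 0.12, "not_working": 0.72},
        "bmi_cat": {"normal": 0.38, "overweight": 0.42, "obese": 0.20},
        "smoking": {"never": 0.42, "former": 0.43, "current": 0.15},
        "past_cv_event": {"no": 0.80, "yes": 0.20},
        "hypertension": {"no": 0.33, "yes": 0.67},
        "diabetes": {"no": 0.88, "yes": 0.12},
        "depression": {"no": 0.89, "yes": 0.11},
        "income_tertile": {"lowest": 0.39, "middle": 0.47, "highest": 0.14},
        "physical_activity": {"high": 0.19, "low": 0.46, "medium": 0.35},
    }


_BASE_INTAKES = {
    "total_dairy": (6.0, np.log(300.0)),
    "vegetables": (5.0, np.log(200.0)),
    "fruits": (5.0, np.log(200.0)),
    "fish": (3.0, np.log(40.0)),
    "meat": (4.0, np.log(100.0)),
    "eggs": (2.5, np.log(25.0)),
    "grains": (6.0, np.log(200.0)),
    "alcohol": (1.5, np.log(50.0)),
    "sugary_processed": (3.0, np.log(80.0)),
    "high_fat_foods": (3.0, np.log(50.0)),
}


def _null_intake_model() -> dict[str, IntakeModel]:
    return {
        g: IntakeModel(shape=shape, log_mean_intercept=mu)
        for g, (shape, mu) in _BASE_INTAKES.items()
    }


def _confounded_intake_model() -> dict[str, IntakeModel]:
    models = _null_intake_model()
    models["total_dairy"].log_mean_coefs = {
        "age_group=70-74": 0.18,
        "age_group=>74": 0.30,
        "sex=female": -0.12,
        "diabetes=yes": 0.10,
        "education=superior": -0.10,
    }
    # fish varies with covariates outside the outcome model: the treatment
    # weights deconfound the exposure only, so co-exposures must not share
    # outcome-relevant confounders for the substitution estimand to be
    # identified by single-exposure weighting
    models["fish"].log_mean_coefs = {
        "physical_activity=high": 0.25,
        "income_tertile=highest": 0.20,
    }
    models["meat"].log_mean_coefs = {"sex=female": -0.25, "smoking=current": 0.15}
    models["vegetables"].log_mean_coefs = {"sex=female": 0.15, "education=superior": 0.15}
    return models


def _confounded_outcome_covariates() -> dict[str, float]:
    return {
        "age_group=70-74": 0.05,
        "age_group=>74": 0.12,
        "sex=female": -0.03,
        "diabetes=yes": 0.05,
        "education=superior": -0.04,
        "depression=yes": 0.03,
    }


def _mar_censoring() -> CensoringModel:
    # ~20% dropout on average, heavier among older, diabetic, male participants
    return CensoringModel(
        intercept=1.75,
        coefs={
            "age_group=70-74": -0.35,
            "age_group=>74": -0.80,
            "sex=female": 0.25,
            "diabetes=yes": -0.40,
            "smoking=current": -0.25,
        },
    )


def _scenario_null(n: int, seed: int, **kw) -> SimulationTruth:
    return SimulationTruth(
        confounder_margins=_uniform_margins(),
        intake_model=_null_intake_model(),
        outcome_model=OutcomeModel(link="identity", intercept=0.30),
        censoring_model=CensoringModel(intercept=1.386),  # ~80% followed
        n=n,
        seed=seed,
        scenario="null",
        **kw,
    )


def _scenario_confounded(n: int, seed: int, **kw) -> SimulationTruth:
    return SimulationTruth(
        confounder_margins=_uniform_margins(),
        intake_model=_confounded_intake_model(),
        outcome_model=OutcomeModel(
            link="identity",
            intercept=0.22,
            food_coefs={"total_dairy": 0.02, "fish": -0.01},
            covariate_coefs=_confounded_outcome_covariates(),
        ),
        censoring_model=_mar_censoring(),
        n=n,
        seed=seed,
        scenario="confounded_positive",
        **kw,
    )


def _scenario_confounded_logit(n: int, seed: int, **kw) -> SimulationTruth:
    return SimulationTruth(
        confounder_margins=_uniform_margins(),
        intake_model=_confounded_intake_model(),
        outcome_model=OutcomeModel(
            link="logit",
            intercept=-1.2,
            food_coefs={"total_dairy": 0.10, "fish": -0.05},
            covariate_coefs={k: 4 * v for k, v in _confounded_outcome_covariates().items()},
        ),
        censoring_model=_mar_censoring(),
        n=n,
        seed=seed,
        scenario="confounded_logit",
        **kw,
    )


def _scenario_table1_like(n: int, seed: int, **kw) -> SimulationTruth:
    truth = _scenario_confounded(n, seed, **kw)
    # margins pooled over the three consumption groups of the motivating study
    truth.confounder_margins = {
        "age_group": {"<70": 1065 / 1746, "70-74": 385 / 1746, ">74": 296 / 1746},
        "sex": {"female": 1006 / 1746, "male": 740 / 1746},
        "education": {"elementary": 1190 / 1746, "high_school": 278 / 1746, "superior": 278 / 1746},
        "occupation": {"high": 85 / 1711, "middle": 192 / 1711, "low": 208 / 1711, "not_working": 1226 / 1711},
        "bmi_cat": {"normal": 664 / 1727, "overweight": 721 / 1727, "obese": 342 / 1727},
        "smoking": {"never": 730 / 1741, "former": 755 / 1741, "current": 256 / 1741},
        "past_cv_event": {"no": 1393 / 1746, "yes": 353 / 1746},
        "hypertension": {"no": 579 / 1746, "yes": 1167 / 1746},
        "diabetes": {"no": 1540 / 1746, "yes": 206 / 1746},
        "depression": {"no": 1544 / 1734, "yes": 190 / 1734},
        "income_tertile": {"lowest": 444 / 1126, "middle": 523 / 1126, "highest": 159 / 1126},
        "physical_activity": {"high": 293 / 1527, "low": 696 / 1527, "medium": 538 / 1527},
    }
    truth.scenario = "table1_like"
    return truth


SCENARIOS = {
    "null": _scenario_null,
    "confounded_positive": _scenario_confounded,
    "confounded_logit": _scenario_confounded_logit,
    "table1_like": _scenario_table1_like,
}


def generate_truth(
    scenario: str = "confounded_positive",
    n: int = 5000,
    seed: int = 0,
    waves: int = 1,
    overrides: Mapping | None = None,
) -> SimulationTruth:
    """Build a fully specified :class:`SimulationTruth` for a named scenario.

    ``overrides`` may replace any top-level field (e.g. a different
    ``outcome_model``) after the scenario template is instantiated; the
    resulting truth is re-validated.
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid scenarios: {sorted(SCENARIOS)}"
        )
    truth = SCENARIOS[scenario](n=n, seed=seed, waves=waves)
    if overrides:
        for key, value in overrides.items():
            if not hasattr(truth, key):
                raise ValueError(f"unknown SimulationTruth field {key!r}")
            setattr(truth, key, value)
        truth.__post_init__()
    return truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _covariate_dummies(covariates: pd.DataFrame, margins) -> pd.DataFrame:
    """Expand categorical covariates to 0/1 indicator columns named cov=level."""
    cols = {}
    for cov, margin in margins.items():
        values = covariates[cov]
        for level in margin:
            cols[f"{cov}={level}"] = (values == level).astype(float)
    return pd.DataFrame(cols, index=covariates.index)


def _draw_intakes(truth: SimulationTruth, dummies: pd.DataFrame, rng) -> pd.DataFrame:
    intakes = {}
    for group in FOOD_GROUPS:
        model = truth.intake_model[group]
        mean = model.mean(dummies)
        intakes[group] = rng.gamma(model.shape, mean / model.shape)
    return pd.DataFrame(intakes, index=dummies.index)


def generate_cohort(truth: SimulationTruth) -> pd.DataFrame:
    """Generate one cohort table from a validated :class:`SimulationTruth`.

    Causal ordering: covariates -> intakes -> outcome -> censoring, with
    censoring depending only on baseline covariates (MAR dropout).  The
    binary outcome ``y`` is missing exactly for participants not followed.
    Bit-identical output for a fixed truth (including seed).
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n
    covariates = pd.DataFrame(index=pd.RangeIndex(n))
    for cov, margin in truth.confounder_margins.items():
        levels = list(margin)
        probs = np.array([margin[l] for l in levels], float)
        covariates[cov] = rng.choice(levels, size=n, p=probs / probs.sum())
    dummies = _covariate_dummies(covariates, truth.confounder_margins)

    intakes = _draw_intakes(truth, dummies, rng)
    # split total dairy into item-level columns (shares sum to 1 per row)
    shares = rng.dirichlet(_DAIRY_SHARE_CONC, size=n)
    items = pd.DataFrame(
        shares * intakes["total_dairy"].to_numpy()[:, None],
        columns=list(DAIRY_ITEMS),
        index=intakes.index,
    )

    energy = intakes.sum(axis=1).to_numpy() + rng.gamma(10.0, 50.0, size=n)
    mmse = 24 + rng.binomial(6, 0.75, size=n)

    p_y = truth.outcome_model.prob(intakes, dummies)
    if np.any((p_y < 0) | (p_y > 1)):
        raise ValueError("outcome model produced probabilities outside [0,1]")
    y = rng.binomial(1, p_y).astype(float)

    p_c = truth.censoring_model.prob_followed(dummies)
    followed = rng.binomial(1, p_c)
    died = (rng.random(n) < 0.01).astype(int)
    followed = np.where(died == 1, 0, followed)
    followup_years = np.where(followed == 1, rng.uniform(3.0, 7.4, size=n), np.nan)

    frame = pd.concat(
        [
            pd.DataFrame({"participant_id": np.arange(1, n + 1)}),
            covariates,
            items,
            intakes,
            pd.DataFrame(
                {
                    "energy_kcal": energy,
                    "mmse": mmse,
                    "followed": followed,
                    "followup_years": followup_years,
                    "died": died,
                }
            ),
        ],
        axis=1,
    )
    frame["y"] = np.where(followed == 1, y, np.nan)
    # CDR-style score consistent with the binary coding (0 healthy, 0.5 impaired)
    frame["cdr_followup"] = np.where(
        frame["followed"] == 1, np.where(frame["y"] == 1, 0.5, 0.0), np.nan
    )

    if truth.waves >= 2:
        intakes_t1 = _draw_intakes(truth, dummies, rng)
        for group in FOOD_GROUPS:
            frame[f"{group}_t1"] = intakes_t1[group]
    return frame


def true_ace(
    truth: SimulationTruth,
    cohort: pd.DataFrame,
    delta: float = 100.0,
    exposure: str = "total_dairy",
) -> float:
    """True average causal effect of adding ``delta`` g/d of ``exposure``.

    Evaluates the known structural model at shifted and observed intakes and
    averages the risk difference over the cohort.  Under the identity link
    this is exactly ``delta/100 * beta_exposure``.
    """
    dummies = _covariate_dummies(cohort, truth.confounder_margins)
    intakes = cohort[list(FOOD_GROUPS)]
    shifted = intakes.copy()
    shifted[exposure] = shifted[exposure] + delta
    p0 = truth.outcome_model.prob(intakes, dummies)
    p1 = truth.outcome_model.prob(shifted, dummies)
    return float(np.mean(p1 - p0))


def write_cohort(cohort: pd.DataFrame, csv_path, dictionary_path=None) -> None:
    """Write a cohort as CSV plus a JSON data dictionary (column -> metadata)."""
    cohort.to_csv(csv_path, index=False)
    if dictionary_path is not None:
        dictionary = {}
        for col in cohort.columns:
            if cohort[col].dtype == object:
                dictionary[col] = {
                    "type": "categorical",
                    "levels": sorted(cohort[col].dropna().unique().tolist()),
                }
            elif col in FOOD_GROUPS or col in DAIRY_ITEMS:
                dictionary[col] = {"type": "continuous", "units": "g/d"}
            elif col == "energy_kcal":
                dictionary[col] = {"type": "continuous", "units": "kcal/d"}
            else:
                dictionary[col] = {"type": "numeric"}
        with open(dictionary_path, "w") as fh:
            json.dump(dictionary, fh, indent=2, sort_keys=True)
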