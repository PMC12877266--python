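"""Weighted binomial marginal structural models and causal effect estimates.

The marginal structural model (MSM) regresses a binary outcome on the
exposure food group plus every other food group composing the diet (the
"all-component" model), fitted by weighted maximum quasi-likelihood with the
combined inverse-probability weights.  Because confounding and informative
dropout are handled by the weights, the outcome model needs no confounder
terms, and its coefficients have a marginal (population-average) causal
interpretation under the usual identification assumptions (consistency,
conditional exchangeability, positivity, no interference).

Two estimands, both risk differences on the probability scale:

* addition effect — the average causal effect (ACE) of raising the exposure
  by delta g/d (default 100) above observed consumption, other food groups
  held at observed values, computed by marginal standardization (g-computation
  over the weighted analysis sample);
* substitution effect — the difference of two addition ACEs from the same
  all-component fit, ACE(dairy) - ACE(substituted food), interpreting an
  isoweight swap of delta g/d.

Sign convention: a positive substitution effect means replacing delta g/d of
the named food with the exposure raises outcome risk.

Parametric 95% confidence intervals are obtained by simulating coefficient
vectors from a multivariate normal at the estimates with the robust
(sandwich) covariance and recomputing the ACE per draw; a delta-method
alternative is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "MarginalStructuralModel",
    "MSMResults",
    "EstimandSpec",
    "EffectEstimate",
    "ace_substitution_leave_one_out",
]

SIGN_CONVENTION = (
    "positive substitution effect = replacing the substituted food with the "
    "exposure (isoweight, delta g/d) raises outcome risk"
)


@dataclass
class EstimandSpec:
    """What to estimate: exposure, increment, estimand type, substitution food."""

    exposure: str
    outcome: str
    delta: float = 100.0
    estimand: str = "addition"
    substitution_food: str | None = None
    link: str = "logit"

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.estimand not in ("addition", "substitution"):
            raise ValueError(f"unknown estimand {self.estimand!r}")
        if self.estimand == "substitution":
            if self.substitution_food is None:
                raise ValueError("substitution estimand requires a substitution food")
            if self.substitution_food == self.exposure:
                raise ValueError("substitution food cannot equal the exposure")


@dataclass
class EffectEstimate:
    """An ACE (risk difference per delta g/d) with its parametric 95% CI."""

    ace: float
    ci_low: float
    ci_high: float
    estimand: str
    exposure: str
    outcome: str
    n: int
    delta: float = 100.0
    substitution_food: str | None = None
    slope_per_delta: float | None = None
    ci_method: str = "simulation"
    sign_convention: str = SIGN_CONVENTION

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.ace <= self.ci_high):
            raise ValueError("CI does not bracket the point estimate")

    def as_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "estimand": self.estimand,
            "substitution_food": self.substitution_food or "",
            "ace_pct": 100.0 * self.ace,
            "ci_low_pct": 100.0 * self.ci_low,
            "ci_high_pct": 100.0 * self.ci_high,
            "n": self.n,
            "ci_method": self.ci_method,
        }

    def __str__(self) -> str:
        what = (
            f"adding {self.delta:g} g/d of {self.exposure}"
            if self.estimand == "addition"
            else f"substituting {self.delta:g} g/d of {self.substitution_food} with {self.exposure}"
        )
        return (
            f"ACE of {what} on {self.outcome}: "
            f"{100 * self.ace:.2f}% (95% CI {100 * self.ci_low:.2f}% to "
            f"{100 * self.ci_high:.2f}%), n={self.n}"
        )


class MarginalStructuralModel:
    """Weighted binomial MSM for a binary outcome and continuous food exposures.

    Parameters
    ----------
    data : cohort table (analysis rows are selected automatically: outcome
        non-missing and weight present/positive).
    outcome : binary 0/1 outcome column.
    exposure : continuous exposure column, g/d.
    other_foods : remaining food-group columns of the all-component model.
    weights : per-row combined IPW weights (unit weights if None).
    family : "binomial" (logit link, default) or "gaussian" (identity link,
        i.e. a weighted linear probability model).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        exposure: str,
        other_foods: list[str],
        weights: pd.Series | None = None,
        family: str = "binomial",
        covariates: list[str] | None = None,
    ):
        if family not in ("binomial", "gaussian"):
            raise ValueError("family must be 'binomial' or 'gaussian'")
        self.data = data
        self.outcome = outcome
        self.exposure = exposure
        self.other_foods = [f for f in other_foods if f != exposure]
        self.covariates = list(covariates or [])
        self.family = family
        self.link = "logit" if family == "binomial" else "identity"

        w = (
            pd.Series(1.0, index=data.index)
            if weights is None
            else pd.Series(weights).reindex(data.index)
        )
        y = data[outcome]
        keep = y.notna() & w.notna() & (w > 0)
        food_cols = [exposure] + self.other_foods
        keep &= data[food_cols].notna().all(axis=1)
        self._rows = data.index[keep]
        if keep.sum() == 0:
            raise ValueError("no analysis rows (missing outcome or weights everywhere)")
        yv = y.loc[self._rows].astype(float)
        if not set(yv.unique()) <= {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        self._y = yv
        self._w = w.loc[self._rows].astype(float)
        # food groups enter the linear predictor in 100 g/d units
        X = data.loc[self._rows, food_cols].astype(float) / 100.0
        for cov in self.covariates:
            X[cov] = data.loc[self._rows, cov].astype(float)
        X.insert(0, "const", 1.0)
        self._X = X

    @classmethod
    def from_dataframe(cls, data, outcome, exposure, other_foods, **kw):
        return cls(data, outcome, exposure, other_foods, **kw)

    def fit(self, cov_type: str = "HC1") -> "MSMResults":
        """Weighted quasi-likelihood fit with robust (sandwich) covariance."""
        if self.family == "binomial":
            model = sm.GLM(
                self._y, self._X, family=sm.families.Binomial(), var_weights=self._w
            )
            try:
                res = model.fit(cov_type=cov_type)
            except Exception as err:
                raise RuntimeError(f"MSM failed to converge: {err}") from err
            if not res.converged:
                raise RuntimeError("MSM IRLS did not converge")
            mu = res.fittedvalues
            if (mu < 1e-12).all() or (mu > 1 - 1e-12).all():
                raise RuntimeError("degenerate fit: complete separation suspected")
        else:
            res = sm.WLS(self._y, self._X, weights=self._w).fit(cov_type=cov_type)
        return MSMResults(model=self, _res=res, cov_type=cov_type)


class MSMResults:
    """Fitted MSM: coefficients, covariances, ACE functionals and summaries."""

    def __init__(self, model: MarginalStructuralModel, _res, cov_type: str):
        self.model = model
        self._res = _res
        self.cov_type = cov_type
        self.params = _res.params
        self.bse = _res.bse
        self.cov_robust = pd.DataFrame(
            np.asarray(_res.cov_params()), index=self.params.index, columns=self.params.index
        )
        self.nobs = int(len(model._y))

    # -- predictions --------------------------------------------------------
    def _predict(self, X: np.ndarray, params: np.ndarray | None = None) -> np.ndarray:
        beta = self.params.to_numpy() if params is None else params
        eta = X @ beta
        return expit(eta) if self.model.link == "logit" else eta

    def predicted_probabilities(self) -> np.ndarray:
        return self._predict(self.model._X.to_numpy())

    # -- ACE functionals -----------------------------------------------------
    def _shifted_design(self, food: str, delta: float) -> np.ndarray:
        X = self.model._X.copy()
        X[food] = X[food] + delta / 100.0
        return X.to_numpy()

    def _ace_value(self, foods: list[tuple[str, float]], params=None) -> float:
        """Weighted-mean predicted-probability contrast for summed food shifts.

        ``foods`` is a list of (food, signed delta) pairs; the returned value
        is sum_k sign_k * mean_w[p(A_k + |delta|) - p(A)].  Under the identity
        link this collapses to sum_k delta_k/100 * beta_k exactly.
        """
        Xn = self.model._X.to_numpy()
        w = self.model._w.to_numpy()
        w = w / w.sum()
        p0 = self._predict(Xn, params)
        total = 0.0
        clamped = 0
        for food, delta in foods:
            X1 = self._shifted_design(food, abs(delta))
            p1 = self._predict(X1, params)
            if self.model.link == "identity":
                out_of_range = ((p1 < 0) | (p1 > 1)).sum() + ((p0 < 0) | (p0 > 1)).sum()
                clamped += int(out_of_range)
            total += np.sign(delta) * float(np.sum(w * (p1 - p0)))
        self._last_clamp_count = clamped
        return total

    def _ace_terms(self, spec: EstimandSpec) -> list[tuple[str, float]]:
        if spec.estimand == "addition":
            return [(spec.exposure, spec.delta)]
        if spec.substitution_food not in self.model._X.columns:
            raise KeyError(
                f"substitution food {spec.substitution_food!r} is not a covariate "
                "of the all-component model"
            )
        return [(spec.exposure, spec.delta), (spec.substitution_food, -spec.delta)]

    def ace(
        self,
        spec: EstimandSpec,
        ci_method: str = "simulation",
        n_draws: int = 10000,
        seed: int | None = 0,
        level: float = 0.95,
    ) -> EffectEstimate:
        """Point estimate and parametric CI for an addition or substitution ACE."""
        foods = self._ace_terms(spec)
        point = self._ace_value(foods)
        if self.model.link == "identity":
            import warnings

            if getattr(self, "_last_clamp_count", 0) > 0:
                warnings.warn(
                    f"{self._last_clamp_count} identity-link predicted probabilities "
                    "outside [0,1] in the ACE contrast"
                )
        low, high = self._ci(foods, point, ci_method, n_draws, seed, level)
        slope = float(
            sum(
                np.sign(delta) * self.params[food] * abs(delta) / 100.0
                for food, delta in foods
            )
        )
        return EffectEstimate(
            ace=point,
            ci_low=min(low, point),
            ci_high=max(high, point),
            estimand=spec.estimand,
            exposure=spec.exposure,
            outcome=spec.outcome,
            n=self.nobs,
            delta=spec.delta,
            substitution_food=spec.substitution_food,
            slope_per_delta=slope,
            ci_method=ci_method,
        )

    def ace_addition(self, exposure=None, delta=100.0, **kw) -> EffectEstimate:
        spec = EstimandSpec(
            exposure=exposure or self.model.exposure,
            outcome=self.model.outcome,
            delta=delta,
            estimand="addition",
        )
        return self.ace(spec, **kw)

    def ace_substitution(self, substitution_food: str, delta=100.0, **kw) -> EffectEstimate:
        spec = EstimandSpec(
            exposure=self.model.exposure,
            outcome=self.model.outcome,
            delta=delta,
            estimand="substitution",
            substitution_food=substitution_food,
        )
        return self.ace(spec, **kw)

    # -- confidence intervals -------------------------------------------------
    def _ci(self, foods, point, method, n_draws, seed, level):
        alpha = (1.0 - level) / 2.0
        cov = self.cov_robust.to_numpy()
        # guard: covariance must be (numerically) PSD
        eigmin = float(np.linalg.eigvalsh((cov + cov.T) / 2.0).min())
        if eigmin < -1e-8 * max(1.0, abs(cov).max()):
            raise ValueError("coefficient covariance is not positive semi-definite")
        if method == "delta":
            grad = self._ace_gradient(foods)
            se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
            z = norm.ppf(1.0 - alpha)
            return point - z * se, point + z * se
        if method != "simulation":
            raise ValueError("ci_method must be 'simulation' or 'delta'")

        rng = np.random.default_rng(seed)
        if self.model.link == "identity":
            # the ACE is linear in the coefficients: simulate it directly
            coef_vec = np.zeros(len(self.params))
            for food, delta in foods:
                coef_vec[self.params.index.get_loc(food)] += delta / 100.0
            mean = float(coef_vec @ self.params.to_numpy())
            sd = float(np.sqrt(max(coef_vec @ cov @ coef_vec, 0.0)))
            draws = rng.normal(mean, sd, size=n_draws)
        else:
            betas = rng.multivariate_normal(
                self.params.to_numpy(), cov, size=n_draws, method="svd"
            )
            Xn = self.model._X.to_numpy()
            w = self.model._w.to_numpy()
            w = w / w.sum()
            draws = np.zeros(n_draws)
            p0 = expit(Xn @ betas.T)  # (n, n_draws)
            for food, delta in foods:
                X1 = self._shifted_design(food, abs(delta))
                p1 = expit(X1 @ betas.T)
                draws += np.sign(delta) * (w @ (p1 - p0))
        return float(np.quantile(draws, alpha)), float(np.quantile(draws, 1.0 - alpha))

    def _ace_gradient(self, foods) -> np.ndarray:
        """Analytic gradient of the ACE functional wrt the coefficients."""
        Xn = self.model._X.to_numpy()
        w = self.model._w.to_numpy()
        w = w / w.sum()
        grad = np.zeros(len(self.params))
        if self.model.link == "identity":
            for food, delta in foods:
                grad[self.params.index.get_loc(food)] += delta / 100.0
            return grad
        beta = self.params.to_numpy()
        p0 = expit(Xn @ beta)
        d0 = p0 * (1 - p0)
        for food, delta in foods:
            X1 = self._shifted_design(food, abs(delta))
            p1 = expit(X1 @ beta)
            d1 = p1 * (1 - p1)
            grad += np.sign(delta) * ((w * d1) @ X1 - (w * d0) @ Xn)
        return grad

    # -- reporting -------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"Marginal structural model ({self.model.family}, {self.model.link} link), "
            f"robust cov: {self.cov_type}",
            f"outcome: {self.model.outcome}   exposure: {self.model.exposure}   "
            f"n = {self.nobs}   ESS = {self.ess():.1f}",
            f"{'term':<24}{'coef/100g':>12}{'robust SE':>12}",
        ]
        for name in self.params.index:
            lines.append(f"{name:<24}{self.params[name]:>12.5f}{self.bse[name]:>12.5f}")
        return "\n".join(lines)

    def ess(self) -> float:
        w = self.model._w.to_numpy()
        return float(w.sum() ** 2 / np.sum(w**2))


def ace_substitution_leave_one_out(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    other_foods: list[str],
    substitution_food: str,
    weights: pd.Series | None = None,
    family: str = "binomial",
    delta: float = 100.0,
    **ace_kwargs,
) -> EffectEstimate:
    """Substitution effect by refitting with the substituted food left out.

    Alternative framing to the coefficient-difference substitution: the
    all-component model is refit without the substituted food, so the
    exposure coefficient absorbs the implicit displacement of the omitted
    group.  Provided for comparison with the primary (same-fit ACE
    difference) estimator; the two agree only when the omitted food is
    uncorrelated with the retained diet.
    """
    if substitution_food == exposure:
        raise ValueError("substitution food cannot equal the exposure")
    if substitution_food not in other_foods:
        raise KeyError(f"{substitution_food!r} is not among the other food groups")
    reduced = [f for f in other_foods if f != substitution_food]
    res = MarginalStructuralModel(
        data, outcome, exposure, reduced, weights=weights, family=family
    ).fit()
    est = res.ace_addition(delta=delta, **ace_kwargs)
    est.estimand = "substitution"
    est.substitution_food = substitution_food
    est.ci_method = est.ci_method + " (leave-one-out refit)"
    return est
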