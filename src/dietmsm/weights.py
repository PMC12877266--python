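"""Stabilized inverse-probability weights for a continuous exposure.

Treatment weights follow the Gaussian density-ratio construction for a
continuous treatment A with confounders L:

    SW_A = f(A) / f(A | L)

where the numerator is a normal density with the marginal mean and SD of A
and the denominator a normal density with mean from a linear model of A on L
and SD equal to that model's residual standard deviation.  Stabilization by
the marginal density keeps mean(SW_A) near 1 and tames the variance of the
weighted estimator.

Censoring weights correct missing-at-random loss to follow-up:

    SW_C = P(C=1) / P(C=1 | L)

with the denominator from a logistic model; they are defined for followed
participants only.  Both weights are truncated at a percentile cap (default
99.5) and multiplied to form the final analysis weight, which is truncated
again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "TreatmentWeightModel",
    "CensoringWeightModel",
    "WeightSet",
    "truncate_weights",
    "combine_weights",
    "effective_sample_size",
]


def effective_sample_size(weights) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2; equals n iff all equal."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / np.sum(w**2))


def truncate_weights(weights, percentile: float = 99.5):
    """Clip weights above the given percentile to the percentile cap.

    The cap is the lower-order-statistic percentile of the supplied weights
    (numpy's "lower" method); values at or below the cap are unchanged.
    Returns (truncated weights, cap).  This convention makes truncation
    exactly idempotent: the cap is itself an observed weight, so re-running
    truncation recomputes the same cap (an interpolated cap would shrink on
    a second pass).
    """
    w = pd.Series(weights, dtype="float64")
    if len(w) == 0:
        raise ValueError("cannot truncate an empty weight vector")
    if not np.all(np.isfinite(w)) or (w <= 0).any():
        raise ValueError("weights must be positive and finite")
    cap = float(np.quantile(w.to_numpy(), percentile / 100.0, method="lower"))
    return w.clip(upper=cap), cap


def _dummy_design(data: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Reference-coded design matrix (intercept + dummies / numeric columns)."""
    parts = [pd.Series(1.0, index=data.index, name="const")]
    for cov in covariates:
        col = data[cov]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col, prefix=cov, prefix_sep="=", drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


@dataclass
class WeightSet:
    """Per-participant weights plus fitting metadata and diagnostics.

    ``frame`` has columns among {sw_a, sw_c, w, incomplete_flag} indexed like
    the cohort.  ``w`` (combined, truncated) is present only after
    :func:`combine_weights`.
    """

    frame: pd.DataFrame
    truncation_percentile: float | None = None
    caps: dict = field(default_factory=dict)
    formulas: dict = field(default_factory=dict)

    def diagnostics(self) -> dict:
        out = {}
        for col in ("sw_a", "sw_c", "w"):
            if col in self.frame.columns:
                w = self.frame[col].dropna()
                out[col] = {
                    "mean": float(w.mean()),
                    "min": float(w.min()),
                    "max": float(w.max()),
                    "ess": effective_sample_size(w),
                    "n": int(len(w)),
                }
        out["truncation_percentile"] = self.truncation_percentile
        out["caps"] = self.caps
        out["formulas"] = self.formulas
        return out

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=True, index_label="row")


class TreatmentWeightModel:
    """Gaussian density-ratio model for stabilized continuous-treatment weights.

    Parameters
    ----------
    data : DataFrame with the exposure (g/d) and confounder columns.
    exposure : name of the continuous exposure column.
    confounders : covariate columns entering the denominator model.
    incomplete : how rows with missing confounders get a weight after being
        excluded from model fitting — "unit" (SW_A = 1, flagged; default),
        "marginal" (numerator-only, ratio 1 as well but flagged distinctly)
        or "drop" (no weight; NaN).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        exposure: str,
        confounders: list[str],
        incomplete: str = "unit",
    ):
        if incomplete not in ("unit", "marginal", "drop"):
            raise ValueError("incomplete must be 'unit', 'marginal' or 'drop'")
        self.data = data
        self.exposure = exposure
        self.confounders = list(confounders)
        self.incomplete = incomplete

    def fit(self) -> "TreatmentWeightResults":
        a = self.data[self.exposure].astype(float)
        complete = self.data[self.confounders].notna().all(axis=1) & a.notna()
        a_fit = a[complete]
        if len(a_fit) < len(self.confounders) + 2:
            raise ValueError("too few complete rows to fit the treatment model")

        mu_marg = float(a_fit.mean())
        sd_marg = float(a_fit.std(ddof=1))
        X = _dummy_design(self.data.loc[complete], self.confounders)
        ols = sm.OLS(a_fit, X).fit()
        sd_cond = float(np.sqrt(ols.scale))
        if sd_cond == 0.0 or sd_marg == 0.0:
            raise ValueError("zero residual SD: exposure is deterministic given L")

        num = norm.pdf(a_fit, loc=mu_marg, scale=sd_marg)
        den = norm.pdf(a_fit, loc=ols.fittedvalues, scale=sd_cond)
        sw = pd.Series(num / den, index=a_fit.index, name="sw_a")
        bad = ~np.isfinite(sw) | (sw <= 0)
        if bad.any():
            raise FloatingPointError(
                f"non-finite treatment weight for rows {list(sw.index[bad])[:5]}"
            )

        frame = pd.DataFrame(index=self.data.index)
        frame["sw_a"] = sw
        frame["incomplete_flag"] = (~complete).astype(int)
        if self.incomplete in ("unit", "marginal"):
            frame.loc[~complete, "sw_a"] = 1.0
        # "drop" leaves NaN for incomplete rows
        return TreatmentWeightResults(
            model=self,
            weightset=WeightSet(
                frame=frame,
                formulas={
                    "numerator": f"Normal({self.exposure}; marginal mean, marginal sd)",
                    "denominator": f"Normal({self.exposure}; OLS on "
                    f"{'+'.join(self.confounders)}, residual sd)",
                    "incomplete_policy": self.incomplete,
                },
            ),
            ols_result=ols,
            marginal_mean=mu_marg,
            marginal_sd=sd_marg,
            conditional_sd=sd_cond,
        )


@dataclass
class TreatmentWeightResults:
    model: TreatmentWeightModel
    weightset: WeightSet
    ols_result: object
    marginal_mean: float
    marginal_sd: float
    conditional_sd: float

    @property
    def sw_a(self) -> pd.Series:
        return self.weightset.frame["sw_a"]

    def summary(self) -> str:
        d = self.weightset.diagnostics()["sw_a"]
        return (
            "Stabilized treatment weights (Gaussian density ratio)\n"
            f"  exposure: {self.model.exposure}\n"
            f"  marginal mean {self.marginal_mean:.2f}, sd {self.marginal_sd:.2f}; "
            f"residual sd {self.conditional_sd:.2f}\n"
            f"  n={d['n']}  mean={d['mean']:.4f}  min={d['min']:.4f}  "
            f"max={d['max']:.4f}  ESS={d['ess']:.1f}"
        )


class CensoringWeightModel:
    """Stabilized inverse-probability-of-censoring weight model.

    Fits a logistic model of the follow-up indicator on baseline covariates
    over the full eligible population; weights are returned for followed
    participants only (non-followed rows contribute to the fit but receive
    no combined weight).
    """

    def __init__(self, data: pd.DataFrame, covariates: list[str], followed: str = "followed"):
        self.data = data
        self.covariates = list(covariates)
        self.followed = followed

    def fit(self) -> "CensoringWeightResults":
        c = self.data[self.followed].astype(float)
        if not set(c.dropna().unique()) <= {0.0, 1.0}:
            raise ValueError("follow-up indicator must be 0/1")
        if c.isna().any():
            raise ValueError("follow-up indicator must be observed for all rows")

        frame = pd.DataFrame(index=self.data.index)
        if (c == 1).all():
            frame["sw_c"] = 1.0
            return CensoringWeightResults(
                model=self, weightset=WeightSet(frame=frame, formulas={"censoring": "no dropout"}),
                logit_result=None, marginal_p=1.0,
            )

        X = _dummy_design(self.data, self.covariates)
        complete = X.notna().all(axis=1)
        try:
            logit = sm.GLM(c[complete], X.loc[complete], family=sm.families.Binomial()).fit()
        except Exception as err:  # pragma: no cover - statsmodels-internal failures
            raise RuntimeError(f"censoring model failed to fit: {err}") from err
        p_hat = logit.fittedvalues
        if (p_hat < 1e-10).any() or (p_hat > 1 - 1e-10).any():
            raise RuntimeError(
                "fitted follow-up probabilities at 0 or 1 (perfect separation); "
                "coarsen the censoring covariates"
            )
        p_marg = float(c[complete].mean())
        sw_c = p_marg / p_hat
        frame["sw_c"] = np.nan
        followed_rows = complete & (c == 1)
        frame.loc[followed_rows, "sw_c"] = sw_c[followed_rows]
        # incomplete-covariate followed rows: marginal-only stabilized weight = 1
        frame.loc[(~complete) & (c == 1), "sw_c"] = 1.0
        return CensoringWeightResults(
            model=self,
            weightset=WeightSet(
                frame=frame,
                formulas={
                    "numerator": "P(C=1) marginal",
                    "denominator": f"logistic(C ~ {'+'.join(self.covariates)})",
                },
            ),
            logit_result=logit,
            marginal_p=p_marg,
        )


@dataclass
class CensoringWeightResults:
    model: CensoringWeightModel
    weightset: WeightSet
    logit_result: object
    marginal_p: float

    @property
    def sw_c(self) -> pd.Series:
        return self.weightset.frame["sw_c"]

    def summary(self) -> str:
        d = self.weightset.diagnostics().get("sw_c", {})
        return (
            "Stabilized censoring weights (followed participants)\n"
            f"  marginal P(followed) = {self.marginal_p:.3f}\n"
            f"  n={d.get('n')}  mean={d.get('mean', float('nan')):.4f}  "
            f"max={d.get('max', float('nan')):.4f}"
        )


def combine_weights(
    sw_a: pd.Series,
    sw_c: pd.Series,
    percentile: float = 99.5,
    truncate_components: bool = True,
) -> WeightSet:
    """Final analysis weight: truncate each component, multiply, truncate again.

    Defined only for participants with both weights (followed participants);
    indices must align.  ``truncate_components=False`` skips the per-component
    truncation and clips only the product.
    """
    both = sw_a.notna() & sw_c.notna()
    ids = sw_a.index[both]
    if len(ids) == 0:
        raise ValueError("no participants with both treatment and censoring weights")
    a, c = sw_a.loc[ids], sw_c.loc[ids]
    caps: dict = {}
    if truncate_components:
        a, caps["sw_a"] = truncate_weights(a, percentile)
        c, caps["sw_c"] = truncate_weights(c, percentile)
    w, caps["w"] = truncate_weights(a * c, percentile)
    frame = pd.DataFrame({"sw_a": sw_a, "sw_c": sw_c})
    frame["w"] = w
    return WeightSet(
        frame=frame,
        truncation_percentile=percentile,
        caps=caps,
        formulas={"combined": "truncate(truncate(SW_A) * truncate(SW_C))"},
    )
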