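"""Binary coding of cognitive outcomes.

Three coding paths:

* clinical dementia rating (CDR): any value above 0 is impairment
  (0.5 corresponds to mild cognitive impairment, 1 to dementia);
* subjective cognitive decline (SCD): questionnaire caseness from item-level
  yes/no responses;
* continuous test scores (verbal fluency, episodic memory, DO40 naming,
  Stroop interference, CERAD praxis): dichotomized at a percentile of the
  observed distribution or at a fixed cutoff, with "impaired = strictly
  below threshold".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OutcomeSpec", "code_cdr", "code_scd", "dichotomize"]

# Fixed cutoffs used for the descriptive stratification of each test
# (score strictly below the cutoff = impaired).
FIXED_CUTOFFS = {
    "verbal_fluency": 36.0,
    "memory": 48.0,
    "do40": 40.0,
    "stroop": 24.0,
    "cerad": 11.0,
}


@dataclass
class OutcomeSpec:
    """Dichotomization rule for one outcome.

    rule is "percentile" (threshold at the given percentile of the observed
    scores, type-7 / linear-interpolation quantile) or "fixed" (threshold is
    ``cutoff``).  Impaired participants score strictly below the threshold;
    ``higher_is_worse=True`` flips the direction for instruments where a
    higher score indicates impairment.
    """

    name: str
    rule: str = "percentile"
    percentile: float = 75.0
    cutoff: float | None = None
    score_range: tuple[float, float] | None = None
    higher_is_worse: bool = False

    def __post_init__(self) -> None:
        if self.rule not in ("percentile", "fixed"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.rule == "fixed":
            if self.cutoff is None:
                raise ValueError("fixed rule requires a cutoff")
            if self.score_range is not None and not (
                self.score_range[0] <= self.cutoff <= self.score_range[1]
            ):
                raise ValueError("cutoff outside the declared score range")


def code_cdr(scores) -> pd.Series:
    """Code clinical dementia rating: impaired (1) iff score > 0.

    Missing scores stay missing; negative scores are invalid.
    """
    s = pd.Series(scores, dtype="float64")
    if (s.dropna() < 0).any():
        raise ValueError("CDR scores must be >= 0")
    out = (s > 0).astype("float64")
    out[s.isna()] = np.nan
    return out


def code_scd(
    responses: pd.DataFrame,
    special_item: str = "item_5",
    clause_items: tuple[str, ...] = ("item_A", "item_4", "item_5", "item_7", "item_8"),
    clause: str = "any",
) -> pd.Series:
    """Code subjective cognitive decline caseness from yes/no item responses.

    A participant is a case if they answered yes to 3 or more items, or to
    the special item, or — depending on ``clause`` — to any (default) or all
    of the configured clause items.  Responses are 0/1 (or boolean); rows
    with any missing required response are flagged missing, never coded 0.
    """
    if clause not in ("any", "all"):
        raise ValueError("clause must be 'any' or 'all'")
    needed = set(clause_items) | {special_item}
    missing_cols = [c for c in needed if c not in responses.columns]
    if missing_cols:
        raise KeyError(f"SCD responses missing items: {missing_cols}")

    resp = responses.astype("float64")
    incomplete = resp.isna().any(axis=1)
    total_yes = resp.sum(axis=1)
    rule_count = total_yes >= 3
    rule_special = resp[special_item] == 1
    clause_frame = resp[list(clause_items)] == 1
    rule_clause = clause_frame.any(axis=1) if clause == "any" else clause_frame.all(axis=1)

    case = (rule_count | rule_special | rule_clause).astype("float64")
    case[incomplete] = np.nan
    return case


def dichotomize(
    scores,
    spec: OutcomeSpec,
    weights=None,
) -> tuple[pd.Series, float]:
    """Dichotomize continuous scores per an :class:`OutcomeSpec`.

    Returns (binary impaired vector, realized threshold).  Under the
    percentile rule the threshold is the type-7 (linear interpolation)
    percentile of the non-missing scores; ``weights`` selects a weighted
    quantile using the same interpolation on the weighted ECDF.  Impairment
    is strict ("score strictly below threshold"), so ties at the threshold
    are coded healthy.
    """
    s = pd.Series(scores, dtype="float64")
    observed = s.dropna()
    if spec.rule == "percentile":
        if observed.nunique() < 2:
            raise ValueError(
                "percentile dichotomization undefined: fewer than 2 distinct scores"
            )
        if weights is None:
            threshold = float(np.quantile(observed, spec.percentile / 100.0))
        else:
            w = pd.Series(weights, dtype="float64").loc[observed.index]
            threshold = _weighted_quantile(
                observed.to_numpy(), w.to_numpy(), spec.percentile / 100.0
            )
    else:
        threshold = float(spec.cutoff)

    if spec.higher_is_worse:
        impaired = (s > threshold).astype("float64")
    else:
        impaired = (s < threshold).astype("float64")
    impaired[s.isna()] = np.nan
    return impaired, threshold


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Weighted quantile with linear interpolation on the normalized ECDF."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= np.sum(w)
    return float(np.interp(q, cw, v))


def default_outcome_specs() -> dict[str, OutcomeSpec]:
    """Percentile-rule specs for the five continuous tests (default mode)."""
    return {
        name: OutcomeSpec(name=name, rule="percentile", percentile=75.0)
        for name in FIXED_CUTOFFS
    }
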