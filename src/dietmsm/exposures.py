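"""Food-group aggregation, eligibility rules and cumulative-average exposures.

Item-level FFQ intakes (g/d) are summed into food groups and dairy subtypes
(fermented / non-fermented, full-fat / low-fat, sugary) according to a
declarative :class:`FoodGroupMap`.  Eligibility screening mirrors a typical
older-adult cohort: age above a cutoff, cognitively healthy at baseline
(MMSE above a cutoff), plausible total energy intake with sex-specific
bounds, and a minimum follow-up interval with a fallback to a later
assessment wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FoodGroupMap",
    "EligibilityCriteria",
    "default_food_group_map",
    "aggregate_food_groups",
    "apply_eligibility",
    "cumulative_average_exposure",
]

DAIRY_SUBTYPES = ("fermented", "non_fermented", "full_fat", "low_fat", "sugary")


@dataclass
class FoodGroupMap:
    """Maps FFQ items to food groups and dairy-subtype memberships.

    Every dairy item must belong to exactly one of {fermented, non_fermented}
    and exactly one of {full_fat, low_fat}; ``sugary`` is an independent flag
    (a flavored yogurt can be both fermented and sugary).  Non-dairy items
    belong to exactly one group.
    """

    items: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item, entry in self.items.items():
            if "group" not in entry:
                raise ValueError(f"item {item!r} has no group")
            if entry["group"] == "dairy":
                subtypes = set(entry.get("subtypes", []))
                ferm = subtypes & {"fermented", "non_fermented"}
                fat = subtypes & {"full_fat", "low_fat"}
                if len(ferm) != 1 or len(fat) != 1:
                    raise ValueError(
                        f"dairy item {item!r} must have exactly one of "
                        "fermented/non_fermented and one of full_fat/low_fat; "
                        f"got {sorted(subtypes)}"
                    )

    @property
    def dairy_items(self) -> list[str]:
        return [i for i, e in self.items.items() if e["group"] == "dairy"]

    def groups(self) -> list[str]:
        return sorted({e["group"] for e in self.items.values()})

    @classmethod
    def from_yaml(cls, path) -> "FoodGroupMap":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(items=payload["items"])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"items": self.items}, fh, sort_keys=True)


def default_food_group_map() -> FoodGroupMap:
    """The packaged default map (editable YAML shipped with the package)."""
    ref = resources.files("dietmsm").joinpath("data/food_group_map.yaml")
    with resources.as_file(ref) as path:
        return FoodGroupMap.from_yaml(path)


def aggregate_food_groups(
    item_intakes: pd.DataFrame, food_map: FoodGroupMap
) -> pd.DataFrame:
    """Sum item-level g/d intakes into group totals and dairy subtypes.

    Returns one column per food group, plus ``total_dairy`` and one column per
    dairy subtype (``dairy_fermented``, ``dairy_non_fermented``,
    ``dairy_full_fat``, ``dairy_low_fat``, ``dairy_sugary``).  Raises on any
    intake column not present in the map, naming the item.
    """
    unmapped = [c for c in item_intakes.columns if c not in food_map.items]
    if unmapped:
        raise KeyError(f"unmapped items in intake table: {unmapped}")
    if (item_intakes < 0).any().any():
        bad = item_intakes.columns[(item_intakes < 0).any()].tolist()
        raise ValueError(f"negative intakes in columns {bad}")

    out = pd.DataFrame(index=item_intakes.index)
    for group in food_map.groups():
        members = [i for i in item_intakes.columns if food_map.items[i]["group"] == group]
        if not members:
            continue
        label = "total_dairy" if group == "dairy" else group
        out[label] = item_intakes[members].sum(axis=1)
    for subtype in DAIRY_SUBTYPES:
        members = [
            i
            for i in item_intakes.columns
            if food_map.items[i]["group"] == "dairy"
            and subtype in food_map.items[i].get("subtypes", [])
        ]
        out[f"dairy_{subtype}"] = (
            item_intakes[members].sum(axis=1) if members else 0.0
        )
    return out


@dataclass
class EligibilityCriteria:
    """Inclusion rules; all bounds are exclusive (strict inequalities)."""

    min_age: float = 59.0  # include if age > min_age
    min_mmse: float = 23.0  # include if MMSE > min_mmse
    kcal_bounds_female: tuple[float, float] = (500.0, 3500.0)
    kcal_bounds_male: tuple[float, float] = (800.0, 4000.0)
    min_followup_years: float = 3.0

    def __post_init__(self) -> None:
        for lo, hi in (self.kcal_bounds_female, self.kcal_bounds_male):
            if not lo < hi:
                raise ValueError("kcal lower bound must be below upper bound")


_REQUIRED_COLS = ("sex", "energy_kcal", "mmse")


def apply_eligibility(
    cohort: pd.DataFrame,
    criteria: EligibilityCriteria | None = None,
    age_col: str = "age_years",
    followup_col: str = "followup_years",
    followup_col_t2: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen a cohort; return (eligible rows, exclusion log).

    Exclusion reasons are assigned in a fixed precedence order — age, mmse,
    kcal, no_followup — recording the first failing rule per participant so
    logs are reproducible.  If a Time-1 follow-up is absent or shorter than
    the minimum interval and a Time-2 interval column is supplied, the Time-2
    assessment is used as the follow-up instead (recorded in the eligible
    table as ``followup_years_used``).

    The returned eligible table is the *eligible-for-weighting* set (passes
    age / MMSE / kcal screens); its ``followed_up`` column distinguishes the
    analysis set (also followed) so weight models can be fit on the full
    eligible population.
    """
    if criteria is None:
        criteria = EligibilityCriteria()
    missing = [c for c in _REQUIRED_COLS if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort missing required columns: {missing}")

    work = cohort.copy()
    reasons = pd.Series(pd.NA, index=work.index, dtype="object")

    if age_col in work.columns:
        fail_age = ~(work[age_col] > criteria.min_age)
        reasons[fail_age & reasons.isna()] = "age"
    fail_mmse = ~(work["mmse"] > criteria.min_mmse)
    reasons[fail_mmse & reasons.isna()] = "mmse"

    female = work["sex"] == "female"
    lo = pd.Series(criteria.kcal_bounds_male[0], index=work.index)
    hi = pd.Series(criteria.kcal_bounds_male[1], index=work.index)
    lo[female] = criteria.kcal_bounds_female[0]
    hi[female] = criteria.kcal_bounds_female[1]
    fail_kcal = (work["energy_kcal"] < lo) | (work["energy_kcal"] > hi)
    reasons[fail_kcal & reasons.isna()] = "kcal"

    # follow-up: use Time 1 if >= minimum interval, else fall back to Time 2
    fu = work[followup_col] if followup_col in work.columns else pd.Series(np.nan, index=work.index)
    used = fu.copy()
    if followup_col_t2 is not None and followup_col_t2 in work.columns:
        t1_bad = fu.isna() | (fu < criteria.min_followup_years)
        used = used.where(~t1_bad, work[followup_col_t2])
    followed = used.notna() & (used >= criteria.min_followup_years)
    work["followup_years_used"] = used.where(followed)
    work["followed_up"] = followed.astype(int)

    excluded = reasons.notna()
    log = pd.DataFrame(
        {
            "participant_id": work.loc[excluded, "participant_id"]
            if "participant_id" in work.columns
            else work.index[excluded],
            "reason": reasons[excluded].to_numpy(),
        }
    ).reset_index(drop=True)
    return work.loc[~excluded].copy(), log


def cumulative_average_exposure(
    intakes_t0: pd.DataFrame, intakes_t1: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Index]:
    """Element-wise mean of two FFQ waves for participants with both waves.

    Participants with any missing wave-1 value are excluded from the
    sensitivity path; their index is returned as the second element so the
    caller can log them.
    """
    if not intakes_t0.columns.equals(intakes_t1.columns):
        raise ValueError("wave tables must share the same food-group columns")
    aligned_t1 = intakes_t1.reindex(intakes_t0.index)
    missing = aligned_t1.isna().any(axis=1) | intakes_t0.isna().any(axis=1)
    avg = (intakes_t0.loc[~missing] + aligned_t1.loc[~missing]) / 2.0
    return avg, intakes_t0.index[missing]
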