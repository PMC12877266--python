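"""Standardized mean difference (SMD) balance diagnostics.

Implements the pooled-variance binary SMD, the Mahalanobis-type multivariate
SMD for multi-level categorical variables (Yang–Dalton construction), and the
two-variance continuous SMD.  For more than two groups the reported SMD is
the arithmetic mean over all unordered group pairs, the convention used by
baseline-characteristics ("Table 1") software.  Weighted variants replace raw
proportions, means and variances with weighted ones (weights treated as
normalized replication counts) to assess covariate balance after inverse
probability weighting; SMD below 0.1 is conventionally considered balanced.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "smd_binary",
    "smd_continuous",
    "smd_categorical",
    "multigroup_smd",
    "weighted_balance",
    "BalanceReport",
]


def smd_binary(p1: float, p2: float) -> float:
    """Pooled-variance SMD between two proportions.

    |p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2).  Returns 0 when both groups
    are degenerate and equal, +inf when both are degenerate and different.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p!r} outside [0,1]")
    pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
    if pooled == 0.0:
        return 0.0 if p1 == p2 else float("inf")
    return abs(p1 - p2) / np.sqrt(pooled)


def smd_continuous(m1: float, s1: float, m2: float, s2: float) -> float:
    """SMD for a continuous variable: |m1 - m2| / sqrt((s1^2 + s2^2)/2)."""
    pooled = (s1**2 + s2**2) / 2.0
    if pooled == 0.0:
        return 0.0 if m1 == m2 else float("inf")
    return abs(m1 - m2) / np.sqrt(pooled)


def smd_categorical(props1, props2) -> float:
    """Mahalanobis-type multivariate SMD between two level-proportion vectors.

    sqrt(d' S^-1 d) with d the difference of the first K-1 level proportions
    and S the average of the two multinomial covariance matrices.  For a
    binary variable treated as 2-level categorical this reduces algebraically
    to :func:`smd_binary`.  Linearly dependent levels making S singular are
    dropped (pseudo-inverse) with a warning.
    """
    p1 = np.asarray(props1, dtype=float)
    p2 = np.asarray(props2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1 or len(p1) < 2:
        raise ValueError("proportion vectors must be 1-d, equal length, >= 2 levels")
    for p in (p1, p2):
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("level proportions must sum to 1")

    d = (p1 - p2)[:-1]

    def mult_cov(p):
        q = p[:-1]
        return np.diag(q) - np.outer(q, q)

    S = (mult_cov(p1) + mult_cov(p2)) / 2.0
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular covariance in categorical SMD; using pseudo-inverse")
        sol = np.linalg.pinv(S) @ d
    val = float(d @ sol)
    return float(np.sqrt(max(val, 0.0)))


def _pairwise_smd(summaries: list, kind: str) -> list[float]:
    out = []
    for a, b in combinations(summaries, 2):
        if kind == "binary":
            out.append(smd_binary(a, b))
        elif kind == "categorical":
            out.append(smd_categorical(a, b))
        elif kind == "continuous":
            out.append(smd_continuous(a[0], a[1], b[0], b[1]))
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
    return out


def multigroup_smd(summaries, kind: str = "binary") -> float:
    """Average pairwise SMD across two or more groups.

    ``summaries`` is one entry per group: a proportion (binary), a level
    proportion vector (categorical) or an (mean, sd) pair (continuous).
    With two groups this is the plain pairwise SMD.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValueError("need at least 2 groups")
    return float(np.mean(_pairwise_smd(summaries, kind)))


def multigroup_smd_from_counts(counts) -> float:
    """Average pairwise categorical SMD from raw per-group level counts.

    Group denominators are the sums of the supplied (non-missing) category
    counts, matching how printed baseline tables are read.  A group with zero
    total raises.
    """
    props = []
    for c in counts:
        c = np.asarray(c, dtype=float)
        if c.sum() <= 0:
            raise ValueError("group with zero total count")
        props.append(c / c.sum())
    if len(props[0]) == 2:
        return multigroup_smd([p[1] for p in props], kind="binary")
    return multigroup_smd(props, kind="categorical")


# ---------------------------------------------------------------------------
# Weighted cohort-level balance
# ---------------------------------------------------------------------------

@dataclass
class BalanceReport:
    """Per-covariate SMDs before and after weighting, with a balance flag."""

    table: pd.DataFrame  # covariate, kind, smd_pre, smd_post, balanced
    grouping: str
    threshold: float = 0.1

    @property
    def max_smd_pre(self) -> float:
        return float(self.table["smd_pre"].max())

    @property
    def max_smd_post(self) -> float:
        return float(self.table["smd_post"].max())

    def unbalanced(self) -> list[str]:
        return self.table.loc[~self.table["balanced"], "covariate"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def render(self) -> str:
        lines = [f"Covariate balance across levels of {self.grouping!r} "
                 f"(threshold {self.threshold})"]
        lines.append(f"{'covariate':<22}{'kind':<14}{'SMD pre':>10}{'SMD post':>10}  flag")
        for _, row in self.table.iterrows():
            flag = "" if row["balanced"] else "  *unbalanced*"
            lines.append(
                f"{row['covariate']:<22}{row['kind']:<14}"
                f"{row['smd_pre']:>10.3f}{row['smd_post']:>10.3f}{flag}"
            )
        return "\n".join(lines)


def _weighted_props(values: pd.Series, weights: np.ndarray, levels) -> np.ndarray:
    total = weights.sum()
    return np.array([weights[(values == lev).to_numpy()].sum() / total for lev in levels])


def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = np.average(x, weights=w)
    var = np.average((x - m) ** 2, weights=w)
    return float(m), float(np.sqrt(var))


def group_summaries(
    cohort: pd.DataFrame,
    covariate: str,
    grouping: pd.Series,
    weights: pd.Series | None = None,
    kind: str | None = None,
):
    """Per-group (optionally weighted) summaries of one covariate.

    Returns (summaries, kind) where summaries feed :func:`multigroup_smd`.
    Rows with a missing covariate value are dropped from that covariate's
    denominators.
    """
    values = cohort[covariate]
    keep = values.notna()
    values = values[keep]
    grp = grouping[keep]
    w = (
        np.ones(len(values))
        if weights is None
        else pd.Series(weights).loc[values.index].to_numpy(float)
    )
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError(f"weights for covariate {covariate!r} must be positive and finite")

    if kind is None:
        kind = "continuous" if pd.api.types.is_numeric_dtype(values) else "categorical"

    summaries = []
    for level in grp.dropna().unique():
        mask = (grp == level).to_numpy()
        if w[mask].sum() == 0:
            raise ValueError(f"grouping level {level!r} has zero total weight")
        if kind == "continuous":
            summaries.append(_weighted_mean_sd(values[mask].to_numpy(float), w[mask]))
        else:
            levels = sorted(values.dropna().unique().tolist())
            props = _weighted_props(values[mask], w[mask], levels)
            props = props / props.sum()
            if len(levels) == 2:
                summaries.append(props[1])
            else:
                summaries.append(props)
    if kind != "continuous":
        kind = "binary" if np.ndim(summaries[0]) == 0 else "categorical"
    return summaries, kind


def weighted_balance(
    cohort: pd.DataFrame,
    weights: pd.Series,
    grouping: pd.Series,
    confounders: list[str],
    threshold: float = 0.1,
) -> BalanceReport:
    """Compare covariate balance across exposure groups before/after weighting.

    ``grouping`` is a categorical exposure grouping (e.g. tertiles of the
    continuous exposure); ``weights`` are the combined IPW weights.  The
    post-weighting SMD for each confounder uses weighted proportions / means
    / variances in the same SMD formulas as the unweighted column.
    """
    rows = []
    for cov in confounders:
        pre_summ, kind = group_summaries(cohort, cov, grouping)
        post_summ, _ = group_summaries(cohort, cov, grouping, weights=weights, kind=None)
        smd_pre = multigroup_smd(pre_summ, kind)
        smd_post = multigroup_smd(post_summ, kind)
        rows.append(
            {
                "covariate": cov,
                "kind": kind,
                "smd_pre": smd_pre,
                "smd_post": smd_post,
                "balanced": smd_post < threshold,
            }
        )
    return BalanceReport(
        table=pd.DataFrame(rows), grouping=str(grouping.name), threshold=threshold
    )
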