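"""Two-sample and k-group comparisons with standardized effect sizes.

Pooled-variance (Student) t tests with Cohen's d for two groups; one-way
ANOVA with omega squared for k groups.  Omega squared is reported unclamped
(it may be slightly negative under the null, which keeps its expectation at
zero); clamp at display time if needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparisonResult",
    "cohens_d",
    "two_sample_t",
    "one_way_anova",
    "omega_squared",
    "compare_measures",
]


@dataclass(frozen=True)
class GroupComparisonResult:
    """One statistical comparison of a measure between groups."""

    test: str  # "t" or "anova"
    statistic: float
    p_value: float
    effect_size: float  # Cohen's d (t) or omega squared (anova)
    group_ns: tuple[int, ...]
    flagged: bool = False  # too few usable subjects in some group


def _as_arrays(*samples) -> list[np.ndarray]:
    return [np.asarray(s, dtype=float).ravel() for s in samples]


def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    return float(
        np.sqrt(
            ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        )
    )


def cohens_d(x, y) -> float:
    """Cohen's d: (mean(x) - mean(y)) / pooled SD."""
    x, y = _as_arrays(x, y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    sp = _pooled_sd(x, y)
    diff = float(x.mean() - y.mean())
    if sp == 0:
        if diff == 0:
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    return diff / sp


def two_sample_t(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t test (pooled variance; Welch by flag).

    Returns (t, p).  Identical samples give (0, 1); zero pooled variance with
    unequal means is an error.
    """
    x, y = _as_arrays(x, y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    sp = _pooled_sd(x, y)
    diff = float(x.mean() - y.mean())
    if sp == 0:
        if diff == 0:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    if welch:
        t, p = sps.ttest_ind(x, y, equal_var=False)
        return float(t), float(p)
    n1, n2 = len(x), len(y)
    se = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
    t = diff / se
    df = n1 + n2 - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def _anova_ss(groups: Sequence[np.ndarray]) -> tuple[float, float, int, int]:
    """Between/within sums of squares and their degrees of freedom."""
    k = len(groups)
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_between = k - 1
    df_within = len(all_values) - k
    return ss_between, ss_within, df_between, df_within


def one_way_anova(*groups) -> tuple[float, float]:
    """One-way ANOVA: F = MSbetween / MSwithin and its upper-tail p.

    All-identical groups give (0, 1); zero within-group variance with unequal
    means is an error.
    """
    groups = _as_arrays(*groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    ssb, ssw, dfb, dfw = _anova_ss(groups)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        raise ValueError("zero within-group variance with unequal means")
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return float(F), p


def omega_squared(*groups) -> float:
    """Omega squared: (SSb - (k-1) MSw) / (SSt + MSw), unclamped."""
    groups = _as_arrays(*groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    ssb, ssw, dfb, dfw = _anova_ss(groups)
    if ssw == 0 and ssb == 0:
        return 0.0
    if ssw == 0:
        raise ValueError("zero within-group variance with unequal means")
    msw = ssw / dfw
    return float((ssb - dfb * msw) / (ssb + ssw + msw))


def compare_measures(
    table: pd.DataFrame,
    measures: Sequence[str],
    group_col: str = "group",
    design: str = "two_group",
    welch: bool = False,
) -> pd.DataFrame:
    """Per-measure group comparison over a cohort table.

    Rows missing a measure are dropped for that measure only.  Two-group
    design: pooled t + Cohen's d (first group minus second, in the order the
    labels appear).  k-group: one-way ANOVA + omega squared.  A measure
    leaving < 2 usable subjects in any group is flagged, not fatal.
    """
    if design not in ("two_group", "k_group"):
        raise ValueError("design must be 'two_group' or 'k_group'")
    labels = list(pd.unique(table[group_col]))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups in the table")
    if design == "two_group" and len(labels) != 2:
        raise ValueError("two_group design needs exactly 2 groups")

    rows = []
    for name in measures:
        samples = [
            table.loc[table[group_col] == lab, name].dropna().to_numpy()
            for lab in labels
        ]
        ns = tuple(len(s) for s in samples)
        if any(n < 2 for n in ns):
            rows.append(
                GroupComparisonResult(
                    test="t" if design == "two_group" else "anova",
                    statistic=np.nan,
                    p_value=np.nan,
                    effect_size=np.nan,
                    group_ns=ns,
                    flagged=True,
                )
            )
            continue
        if design == "two_group":
            t, p = two_sample_t(samples[0], samples[1], welch=welch)
            d = cohens_d(samples[0], samples[1])
            rows.append(GroupComparisonResult("t", t, p, d, ns))
        else:
            F, p = one_way_anova(*samples)
            w2 = omega_squared(*samples)
            rows.append(GroupComparisonResult("anova", F, p, w2, ns))

    out = pd.DataFrame(
        {
            "measure": list(measures),
            "test": [r.test for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_value": [r.p_value for r in rows],
            "effect_size": [r.effect_size for r in rows],
            "flagged": [r.flagged for r in rows],
        }
    )
    for j, lab in enumerate(labels):
        out[f"n_{lab}"] = [r.group_ns[j] for r in rows]
    return out
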