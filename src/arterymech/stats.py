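"""Group summaries and hypothesis tests for three-group comparisons.

Conventions follow standard practice in vascular biomechanics reporting:
mean ± SEM for biomechanical quantities, mean ± SD for image-derived ones;
one-way ANOVA across groups with Bonferroni-corrected pairwise t tests post
hoc, significance at p < 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± dispersion of one group, with the convention recorded."""

    label: str
    n: int
    mean: float
    dispersion: float
    convention: Literal["SEM", "SD"]
    flagged_zero: bool = False  # n == 1: dispersion reported as 0 by convention


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    t_statistic: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: tuple[PairwiseComparison, ...] = ()


def summarize(
    values: Sequence[float],
    convention: Literal["SEM", "SD"] = "SEM",
    label: str = "",
) -> GroupSummary:
    """Mean ± SEM or ± SD (sample SD, n−1) of one group.

    A single value has undefined dispersion; it is reported as 0 with
    ``flagged_zero`` set so tables always render.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise InsufficientDataError("cannot summarize an empty group")
    if v.size == 1:
        return GroupSummary(label, 1, float(v[0]), 0.0, convention, True)
    sd = float(v.std(ddof=1))
    disp = sd / math.sqrt(v.size) if convention == "SEM" else sd
    return GroupSummary(label, int(v.size), float(v.mean()), disp, convention)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA: F = MSB/MSW, p from the F distribution."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise InsufficientDataError("ANOVA needs at least two groups")
    if any(g.size < 2 for g in gs):
        raise InsufficientDataError("every group needs n >= 2")
    if all(np.ptp(g) == 0 for g in gs) and np.ptp([g[0] for g in gs]) == 0:
        raise ZeroDivisionError(
            "all observations identical: F is undefined (0/0)"
        )
    f, p = sps.f_oneway(*gs)
    k = len(gs)
    n = sum(g.size for g in gs)
    return AnovaResult(
        f_statistic=float(f),
        df_between=k - 1,
        df_within=n - k,
        p_value=float(p),
    )


def bonferroni_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    equal_var: bool = True,
) -> tuple[PairwiseComparison, ...]:
    """All pairwise two-sample t tests with Bonferroni adjustment.

    Adjusted p = min(1, m·p) with m the number of pairs.  ``equal_var=False``
    switches to Welch tests.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise InsufficientDataError("need at least two groups")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(gs))]
    pairs = list(itertools.combinations(range(len(gs)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        t, p = sps.ttest_ind(gs[i], gs[j], equal_var=equal_var)
        out.append(
            PairwiseComparison(
                pair=(labels[i], labels[j]),
                t_statistic=float(t),
                p_raw=float(p),
                p_adjusted=min(1.0, m * float(p)),
            )
        )
    return tuple(out)


def anova_with_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    equal_var: bool = True,
) -> AnovaResult:
    """One-way ANOVA followed by Bonferroni pairwise t tests."""
    res = one_way_anova(groups)
    return AnovaResult(
        f_statistic=res.f_statistic,
        df_between=res.df_between,
        df_within=res.df_within,
        p_value=res.p_value,
        pairwise=bonferroni_pairwise(groups, labels, equal_var),
    )


def build_group_table(
    per_specimen: pd.DataFrame,
    convention: Literal["SEM", "SD"] = "SEM",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tidy comparison table: metric × group → mean, dispersion, n,
    pairwise significance flags.

    ``per_specimen`` is tidy with columns ``group``, ``metric``, ``value``
    (one row per specimen and metric).  Metrics missing for a group emit a
    row with NaN mean and n = 0 (explicit gap marker).  Significance stars
    come from Bonferroni-adjusted pairwise t tests at ``alpha`` when every
    group has n ≥ 2.
    """
    required = {"group", "metric", "value"}
    if not required.issubset(per_specimen.columns):
        raise ValueError(f"per-specimen table needs columns {sorted(required)}")
    groups = sorted(per_specimen["group"].unique())
    metrics = sorted(per_specimen["metric"].unique())
    rows = []
    for metric in metrics:
        sub = per_specimen[per_specimen["metric"] == metric]
        by_group = {
            g: sub.loc[sub["group"] == g, "value"].to_numpy() for g in groups
        }
        testable = [g for g in groups if len(by_group[g]) >= 2]
        sig: dict[str, str] = {g: "" for g in groups}
        if len(testable) >= 2:
            comps = bonferroni_pairwise(
                [by_group[g] for g in testable], labels=testable
            )
            for c in comps:
                if c.p_adjusted < alpha:
                    a, b = c.pair
                    sig[a] = (sig[a] + f"*{b}") if sig[a] else f"*{b}"
                    sig[b] = (sig[b] + f"*{a}") if sig[b] else f"*{a}"
        for g in groups:
            v = by_group[g]
            if len(v) == 0:
                rows.append(
                    dict(metric=metric, group=g, mean=np.nan, dispersion=np.nan,
                         n=0, convention=convention, significant_vs="")
                )
                continue
            s = summarize(v, convention, g)
            rows.append(
                dict(metric=metric, group=g, mean=s.mean, dispersion=s.dispersion,
                     n=s.n, convention=convention, significant_vs=sig[g])
            )
    return pd.DataFrame(rows)
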