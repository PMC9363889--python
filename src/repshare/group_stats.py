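"""Group-level aggregation and hypothesis tests for overlap/summary metrics.

The module's job is the mapping from study comparisons onto standard
tests — which metric, which groups, paired on what key, two-sided —
not novel statistics; the computations delegate to scipy/statsmodels.

Conventions: sample SD uses the n-1 denominator and is undefined (NaN)
for n=1 groups; all tests are two-sided by default with p < 0.05 called
significant; the Mann-Whitney U statistic reported is the U of the
first group (scipy's convention, so fully separated groups give U = 0
or U = n1*n2 depending on direction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparison", "aggregate", "compare", "anova_tukey"]

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class GroupComparison:
    """Result of one two-group test on a metric."""

    metric: str
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < SIGNIFICANCE_LEVEL


def aggregate(table: pd.DataFrame, value: str, by: str | Sequence[str]) -> pd.DataFrame:
    """Mean, sample SD (n-1) and n of ``value`` per group of ``by``.

    Groups with a single observation report SD as NaN (undefined), not 0.
    """
    if table.empty:
        raise ValueError("aggregate: empty input")
    by = [by] if isinstance(by, str) else list(by)
    for col in by + [value]:
        if col not in table.columns:
            raise ValueError(f"aggregate: unknown column {col!r}")
    g = table.groupby(by, sort=True)[value]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out.loc[out["n"] < 2, "sd"] = np.nan
    return out


def _describe(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else np.nan


def compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: Literal["paired_t", "mann_whitney_u"],
    *,
    metric: str = "value",
    group_a: str = "a",
    group_b: str = "b",
    alternative: str = "two-sided",
) -> GroupComparison:
    """Two-group comparison: paired t test or unpaired Mann-Whitney U.

    Paired tests require equal-length vectors already aligned on the
    pairing key (same patient / sample pair in both groups); vectors of
    different length are an error. Zero-variance paired differences are
    flagged degenerate and get no p-value rather than a fabricated one.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("compare: empty group")
    mean_a, sd_a = _describe(a)
    mean_b, sd_b = _describe(b)
    degenerate = False
    if test == "paired_t":
        if len(a) != len(b):
            raise ValueError(
                f"paired_t requires aligned equal-length groups, got {len(a)} vs {len(b)}"
            )
        diff = a - b
        if np.allclose(diff, diff[0]) and np.isclose(np.var(diff), 0.0):
            statistic, p_value, degenerate = np.nan, np.nan, True
        else:
            res = stats.ttest_rel(a, b, alternative=alternative)
            statistic, p_value = float(res.statistic), float(res.pvalue)
    elif test == "mann_whitney_u":
        res = stats.mannwhitneyu(a, b, alternative=alternative)
        statistic, p_value = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        test=test,
        statistic=statistic,
        p_value=p_value,
        n_a=len(a),
        n_b=len(b),
        mean_a=mean_a,
        sd_a=sd_a,
        mean_b=mean_b,
        sd_b=sd_b,
        degenerate=degenerate,
    )


def anova_tukey(table: pd.DataFrame, value: str, group: str) -> pd.DataFrame:
    """One-way ANOVA followed by Tukey's multiple-comparison test.

    Returns one row per group pair with the Tukey-adjusted p-value plus
    the family-level ANOVA F and p attached to every row. Typical
    families here are the compartment sets {ST_SP, ST_IP, PB} and
    {ST, SF, PB}.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = [g[value].to_numpy(dtype=float) for _, g in table.groupby(group, sort=True)]
    if len(groups) < 2:
        raise ValueError("anova_tukey needs >= 2 groups")
    f_stat, f_p = stats.f_oneway(*groups)
    tk = pairwise_tukeyhsd(
        table[value].to_numpy(dtype=float), table[group].to_numpy(), alpha=SIGNIFICANCE_LEVEL
    )
    out = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    out = out.rename(
        columns={"group1": "group_a", "group2": "group_b", "p-adj": "p_value", "meandiff": "mean_diff"}
    )[["group_a", "group_b", "mean_diff", "p_value", "reject"]]
    out["anova_F"] = float(f_stat)
    out["anova_p"] = float(f_p)
    out["metric"] = value
    return out
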