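"""Descriptive statistics, automatic design selection, t-tests and Cohen's d.

The analysed effect in differential conditioning is the within-subject
difference score CS1 - CS2.  Without a group column the design is a paired
(one-sample-on-differences) t-test; with a two-level group column the two
groups' difference scores are compared with a classical pooled-variance
independent-samples t-test, so that the degrees of freedom match the
effective-sample-size algebra of the default Bayesian test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from condlab.data import ConditioningTable

__all__ = [
    "FreqResult",
    "select_test",
    "descriptives",
    "paired_ttest",
    "independent_ttest",
    "cohen_d_from_t",
    "run_frequentist",
]


@dataclass
class FreqResult:
    """Result of a paired or independent-samples t-test.

    ``mean_diff`` is mean(CS1 - CS2) for the paired design and the
    group1 - group2 difference of mean difference scores for the
    independent design.  ``ci95`` is the central-t 95% interval for
    ``mean_diff`` at the test's degrees of freedom.
    """

    test_name: str  # "paired" | "independent"
    t: float
    nu: int
    p: float
    mean_diff: float
    ci95: tuple[float, float]
    cohen_d: float
    n: Union[int, tuple[int, int]]


def select_test(table: ConditioningTable) -> str:
    """Choose the design from the data: paired without a group column,
    independent (on difference scores) with a two-level group column."""
    return "independent" if table.group is not None else "paired"


def descriptives(table: ConditioningTable) -> pd.DataFrame:
    """Per-stimulus (and per-group) mean, sd (n-1 denominator), se and n."""
    rows = []

    def block(label_group, cs1, cs2):
        for stim, x in (("cs1", cs1), ("cs2", cs2)):
            n = len(x)
            sd = float(np.std(x, ddof=1))
            rows.append(
                {
                    "group": label_group,
                    "stimulus": stim,
                    "mean": float(np.mean(x)),
                    "sd": sd,
                    "se": sd / np.sqrt(n),
                    "n": n,
                }
            )

    if table.group is None:
        block("all", table.cs1, table.cs2)
    else:
        for lev in table.group_levels:  # type: ignore[union-attr]
            mask = table.group == lev
            block(str(lev), table.cs1[mask], table.cs2[mask])
    return pd.DataFrame(rows)


def _ci95(mean: float, se: float, nu: int) -> tuple[float, float]:
    q = stats.t.ppf(0.975, nu)
    return (mean - q * se, mean + q * se)


def paired_ttest(table: ConditioningTable) -> FreqResult:
    """Paired-samples t-test on the difference scores d_i = cs1_i - cs2_i.

    t = mean(d) / (sd(d)/sqrt(n)), nu = n - 1, two-sided p from the central
    Student-t tail, Cohen's d = mean(d)/sd(d) = t/sqrt(n).

    Raises
    ------
    ValueError
        If a group column is present or the difference scores have zero
        variance (the statistic is undefined).
    """
    if table.group is not None:
        raise ValueError("table has a group column; use the independent design")
    d = table.diffs()
    n = len(d)
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise ValueError("zero-variance difference scores: t statistic undefined")
    mean = float(np.mean(d))
    se = sd / np.sqrt(n)
    t = mean / se
    nu = n - 1
    p = 2.0 * stats.t.sf(abs(t), nu)
    return FreqResult(
        test_name="paired",
        t=float(t),
        nu=nu,
        p=float(p),
        mean_diff=mean,
        ci95=_ci95(mean, se, nu),
        cohen_d=mean / sd,
        n=n,
    )


def independent_ttest(
    group1: Sequence[float], group2: Sequence[float]
) -> FreqResult:
    """Pooled-variance two-sample t-test on per-group difference scores.

    nu = n1 + n2 - 2; Cohen's d = (mean1 - mean2)/sd_pooled.
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    nu = n1 + n2 - 2
    ss = (n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)
    sd_pooled = float(np.sqrt(ss / nu))
    if sd_pooled == 0.0:
        raise ValueError("zero pooled variance: t statistic undefined")
    mean = float(np.mean(x1) - np.mean(x2))
    se = sd_pooled * np.sqrt(1.0 / n1 + 1.0 / n2)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), nu)
    return FreqResult(
        test_name="independent",
        t=float(t),
        nu=nu,
        p=float(p),
        mean_diff=mean,
        ci95=_ci95(mean, se, nu),
        cohen_d=mean / sd_pooled,
        n=(n1, n2),
    )


def cohen_d_from_t(t: float, n1: int, n2: Optional[int] = None) -> float:
    """Cohen's d recovered from a t statistic.

    Paired/one-sample: d = t/sqrt(n1); independent: d = t*sqrt(1/n1 + 1/n2).
    """
    if n2 is None:
        return t / np.sqrt(n1)
    return t * np.sqrt(1.0 / n1 + 1.0 / n2)


def run_frequentist(table: ConditioningTable) -> FreqResult:
    """Run the automatically selected t-test for the table's design."""
    if select_test(table) == "paired":
        return paired_ttest(table)
    g1, g2 = table.diffs_by_group()
    return independent_ttest(g1, g2)
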