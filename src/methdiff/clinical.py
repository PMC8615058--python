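"""Descriptive cohort statistics: Pearson chi-square on categorical counts and
two-sample t-tests from printed group summaries (mean, SD, n)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupSummary", "chisq_test", "ttest_from_summary"]


@dataclass
class GroupSummary:
    """Printed summary of a quantitative variable in one group."""

    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.group!r}: n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def chisq_test(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (X^2, df, p).

    All-zero columns (categories observed in no group) are dropped before
    testing, so df = (rows - 1) * (non-empty columns - 1).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 non-empty columns")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def ttest_from_summary(a: GroupSummary, b: GroupSummary, variant: str = "pooled") -> tuple[float, float, float]:
    """Two-sample t-test from group summaries only: (t, df, p).

    ``variant`` is ``pooled`` (classical Student) or ``welch``.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)
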