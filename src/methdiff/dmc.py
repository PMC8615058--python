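"""Differentially methylated CpG (DMC) calling between two sample groups.

Each retained CpG is tested with a two-sample Student's t-test (pooled
variance by default, Welch optional) on methylation ratios; p-values are
FDR-adjusted by Benjamini-Hochberg across all tested sites, and a site is a
DMC when q < alpha and the group difference |delta| >= min_delta (8% by
default). delta is mean(case) - mean(control), so a hypomethylated DMC has
lower methylation in patients.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .preprocess import PipelineConfig, RatioMatrix

__all__ = ["ttest_site", "bh_adjust", "call_dmcs", "cluster_samples", "COMPARISONS"]

# comparison name -> (case labels, control labels)
COMPARISONS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "MD_vs_control": (("MDH", "MDL"), ("control",)),
    "MDH_vs_control": (("MDH",), ("control",)),
    "MDL_vs_control": (("MDL",), ("control",)),
    "MDH_vs_MDL": (("MDH",), ("MDL",)),
}

_P_FLOOR = 1e-300


def _ttest_matrix(case: np.ndarray, ctrl: np.ndarray, welch: bool = False):
    """Vectorised two-sample t over rows. Returns (t, p, delta)."""
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >=2 samples (got {n1} and {n2})")
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    v1, v2 = case.var(axis=1, ddof=1), ctrl.var(axis=1, ddof=1)
    delta = m1 - m2
    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            t = delta / np.sqrt(se2)
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        df = np.full_like(delta, float(n1 + n2 - 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero_var = ~np.isfinite(t)
    eq = zero_var & (delta == 0)
    ne = zero_var & (delta != 0)
    t = np.where(eq, 0.0, t)
    p = np.empty_like(delta)
    ok = ~zero_var
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    p[eq] = 1.0
    # zero variance with unequal means: p underflows; clamp and sign t
    p[ne] = _P_FLOOR
    t[ne] = np.sign(delta[ne]) * np.inf
    return t, p, delta


def ttest_site(case: Sequence[float], ctrl: Sequence[float], welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test on one site's ratios: (t, p_raw, delta).

    Pooled-variance Student's t by default. Zero pooled variance with equal
    means gives t=0, p=1; with unequal means p is clamped to 1e-300.
    """
    case = np.asarray(case, dtype=float)[None, :]
    ctrl = np.asarray(ctrl, dtype=float)[None, :]
    t, p, d = _ttest_matrix(case, ctrl, welch=welch)
    return float(t[0]), float(p[0]), float(d[0])


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_dmcs(
    ratios: RatioMatrix,
    comparison: str = "MD_vs_control",
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Test every site and flag significant DMCs.

    Returns the full per-site table with columns chrom, pos, delta, t, p, q,
    direction, significant. By default BH runs across all tested sites and the
    effect-size floor is applied afterwards; ``config.filter_then_fdr``
    restricts BH to sites already passing the floor.
    """
    config = config or PipelineConfig()
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}; choose from {sorted(COMPARISONS)}")
    case_labels, ctrl_labels = COMPARISONS[comparison]
    case = ratios.group_columns(case_labels)
    ctrl = ratios.group_columns(ctrl_labels)
    t, p, delta = _ttest_matrix(case, ctrl, welch=config.welch)

    table = ratios.sites.copy()
    table["delta"] = delta
    table["t"] = t
    table["p"] = p
    if config.filter_then_fdr:
        q = np.full(len(p), np.nan)
        sel = np.abs(delta) >= config.min_delta
        if sel.any():
            q[sel] = bh_adjust(p[sel])
        table["q"] = q
        table["significant"] = sel & (q < config.alpha)
    else:
        table["q"] = bh_adjust(p)
        table["significant"] = (table["q"] < config.alpha) & (np.abs(delta) >= config.min_delta)
    table["direction"] = np.where(delta < 0, "hypo", "hyper")
    return table


def chromosome_summary(dmc_table: pd.DataFrame) -> pd.DataFrame:
    """Counts of significant hypo/hyper DMCs per chromosome."""
    sig = dmc_table[dmc_table["significant"]]
    out = (
        sig.groupby(["chrom", "direction"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["hypo", "hyper"], fill_value=0)
        .reset_index()
    )
    out["total"] = out["hypo"] + out["hyper"]
    return out


def cluster_samples(
    ratios: RatioMatrix, dmc_table: pd.DataFrame, top_k: int = 150, n_clusters: int = 2
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Hierarchically cluster samples on the top-|delta| sites.

    Average-linkage agglomeration on euclidean distance over the ``top_k``
    sites ranked by |delta| (e.g. the 150 most differential CpGs for a
    heatmap). Returns (linkage matrix, flat labels at ``n_clusters``, the
    selected site rows).
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if top_k > len(dmc_table):
        raise ValueError(f"top_k={top_k} exceeds {len(dmc_table)} tested sites")
    order = np.argsort(-np.abs(dmc_table["delta"].to_numpy()), kind="mergesort")[:top_k]
    sub = ratios.ratio[np.sort(order)]
    Z = linkage(sub.T, method="average", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, labels, dmc_table.iloc[np.sort(order)]
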