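"""Category enrichment of DMC-bearing genes with CpG-count bias correction.

Genes with more CpGs have more chances to contain a DMC, and genes whose DMCs
show large methylation differences are detected more easily; both distort
naive enrichment tests. Each gene therefore receives a bias value

    bias = nCpGs + nDMC / sum|dDM|            (nCpGs for genes with no DMC)

i.e. its CpG count after filtering plus the inverse of the mean absolute
differential methylation over its DMCs. A monotone probability-weighting
function (isotonic regression of the DMC indicator on the bias rank) converts
bias into a per-gene detection weight, and category over/under-representation
is tested with the Wallenius noncentral hypergeometric distribution whose
odds are the mean weight inside the category over the mean weight outside —
reducing to the exact Fisher/hypergeometric test when weights are equal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, nchypergeom_wallenius
from sklearn.isotonic import IsotonicRegression

from .dmc import bh_adjust

__all__ = ["compute_bias", "fit_pwf", "wallenius_test", "enrichment_table", "read_category_map"]

_WEIGHT_FLOOR = 1e-6


def compute_bias(gene_cpgs: pd.Series, dmc_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene bias values.

    Parameters
    ----------
    gene_cpgs:
        CpG count per gene after filtering (index = gene id).
    dmc_table:
        One row per significant DMC with columns ``gene_id`` and ``delta``;
        a DMC hitting several genes appears once per gene.

    Returns a BiasTable frame: gene_id, n_cpgs, n_dmc, sum_abs_dm, bias.
    """
    genes = gene_cpgs.index
    n_dmc = pd.Series(0, index=genes, dtype=int)
    sum_abs = pd.Series(0.0, index=genes)
    if len(dmc_table):
        grp = dmc_table.groupby("gene_id")["delta"]
        counts = grp.size()
        sums = grp.apply(lambda d: float(np.abs(d).sum()))
        n_dmc.loc[counts.index.intersection(genes)] = counts
        sum_abs.loc[sums.index.intersection(genes)] = sums
    bad = (n_dmc > 0) & (sum_abs == 0)
    if bad.any():
        raise ValueError(f"gene(s) with DMCs but zero total |dDM|: {list(genes[bad])[:5]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        second = np.where(n_dmc > 0, n_dmc / sum_abs.replace(0, np.nan), 0.0)
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "n_cpgs": gene_cpgs.to_numpy(),
            "n_dmc": n_dmc.to_numpy(),
            "sum_abs_dm": sum_abs.to_numpy(),
            "bias": gene_cpgs.to_numpy(dtype=float) + np.nan_to_num(second),
        }
    ).reset_index(drop=True)
    return out


def fit_pwf(de: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Monotone probability-weighting function: weight per gene.

    Isotonic (pool-adjacent-violators) regression of the 0/1
    differentially-methylated indicator on the bias rank, increasing, floored
    at 1e-6. Requires both classes present and at least 10 genes.
    """
    de = np.asarray(de, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if len(de) < 10:
        raise ValueError("need at least 10 genes to fit a weighting function")
    if de.min() == de.max():
        raise ValueError("need both DM and non-DM genes to fit the weighting function")
    rank = pd.Series(bias).rank(method="average").to_numpy()
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    w = iso.fit_transform(rank, de)
    return np.maximum(w, _WEIGHT_FLOOR)


def wallenius_test(
    category: set[str], de_genes: set[str], weights: pd.Series
) -> tuple[float, float]:
    """Over/under-representation p-values for one category.

    ``weights`` indexes the whole gene universe. The Wallenius odds parameter
    is mean weight inside the category over mean weight outside; sampling
    ``n_de`` genes without replacement, the observed count of DE genes inside
    the category is compared with the noncentral hypergeometric tails:
    ``p_over = P(X >= x)``, ``p_under = P(X <= x)``. With equal weights this
    is the exact hypergeometric (Fisher) test.
    """
    universe = set(weights.index)
    if not category:
        raise ValueError("empty category")
    if not category <= universe:
        raise ValueError("category contains genes outside the universe")
    M = len(universe)
    n_cat = len(category)
    n_de = len(de_genes & universe)
    x = len(de_genes & category)
    if n_cat == M:
        return 1.0, 1.0
    w_in = float(weights.loc[sorted(category)].mean())
    w_out = float(weights.loc[sorted(universe - category)].mean())
    odds = w_in / w_out
    if abs(odds - 1.0) < 1e-12:
        p_over = float(hypergeom.sf(x - 1, M, n_cat, n_de))
        p_under = float(hypergeom.cdf(x, M, n_cat, n_de))
    else:
        p_over = float(nchypergeom_wallenius.sf(x - 1, M, n_cat, n_de, odds))
        p_under = float(nchypergeom_wallenius.cdf(x, M, n_cat, n_de, odds))
    return min(p_over, 1.0), min(p_under, 1.0)


def enrichment_table(
    categories: dict[str, set[str]],
    de_genes: set[str],
    bias_table: pd.DataFrame,
) -> pd.DataFrame:
    """Ranked enrichment results over all categories.

    ``categories`` maps category id to member gene ids; genes unknown to the
    bias table are dropped from categories with a warning column. The gene
    universe is the bias table. Output columns: category, n_dm_in_cat,
    n_in_cat, ratio, p_over, p_under, q_over, q_under, dm_genes.
    """
    universe = set(bias_table["gene_id"])
    de_genes = {g for g in de_genes if g in universe}
    weights = pd.Series(
        fit_pwf(bias_table["gene_id"].isin(de_genes).to_numpy(), bias_table["bias"].to_numpy()),
        index=bias_table["gene_id"],
    )
    rows = []
    for cat_id, members in categories.items():
        kept = {g for g in members if g in universe}
        if not kept:
            continue
        p_over, p_under = wallenius_test(kept, de_genes, weights)
        dm = sorted(de_genes & kept)
        rows.append(
            {
                "category": cat_id,
                "n_dm_in_cat": len(dm),
                "n_in_cat": len(kept),
                "ratio": len(dm) / len(kept),
                "p_over": p_over,
                "p_under": p_under,
                "dm_genes": ",".join(dm),
                "n_dropped": len(members) - len(kept),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_over"] = bh_adjust(out["p_over"].to_numpy())
        out["q_under"] = bh_adjust(out["p_under"].to_numpy())
        out = out.sort_values("p_over", kind="mergesort").reset_index(drop=True)
    return out


def read_category_map(path) -> dict[str, set[str]]:
    """Read a two-column TSV (category id, gene id) into a membership map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["category", "gene_id"], dtype=str, comment="#")
    out: dict[str, set[str]] = {}
    for cat, sub in df.groupby("category"):
        out[cat] = set(sub["gene_id"].str.upper())
    return out
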