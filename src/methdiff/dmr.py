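"""Differentially methylated region (DMR) calling.

Per-site p-values are first corrected by their neighbours: each site's p is
combined, by the unweighted Stouffer method, with the p-values of all sites
within a fixed distance (200 bp) on the same chromosome, then adjusted for
multiplicity across all sites (Benjamini-Hochberg), mirroring the FDR
criterion of the per-site stage. Runs of neighbouring significant sites with
a consistent sign of the group difference are then merged, and a run is
reported as a DMR when it contains at least two DMCs (|delta| >= 8%), its
mean difference passes the same floor, and its region p-value is below alpha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dmc import bh_adjust
from .io_formats import GeneModel
from .preprocess import PipelineConfig

__all__ = ["combine_neighbor_pvalues", "merge_dmrs", "annotate_region_promoters"]

_P_LO, _P_HI = 1e-300, 1.0 - 1e-16


def combine_neighbor_pvalues(sites: pd.DataFrame, distance: int = 200) -> np.ndarray:
    """Stouffer-combine each site's p with its neighbours within ``distance`` bp.

    ``sites`` needs sorted (chrom, pos) plus a ``p`` column with p in (0, 1].
    For site i with neighbour set N(i) = {j on same chrom, |pos_j - pos_i| <=
    distance} (including i), the combined statistic is
    ``Z* = sum_j z_j / sqrt(|N(i)|)`` with ``z_j = Phi^{-1}(1 - p_j)`` and the
    adjusted p is ``1 - Phi(Z*)``. An isolated site keeps its p unchanged;
    ``distance=0`` is the identity map.
    """
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    if len(sites) > 1:
        same = chrom[1:] == chrom[:-1]
        if (same & (np.diff(pos) <= 0)).any():
            raise ValueError("sites must be sorted by (chrom, pos)")
        block_chroms = np.concatenate([[chrom[0]], chrom[1:][~same]])
        if len(set(block_chroms)) != len(block_chroms):
            raise ValueError("sites must be grouped by chromosome")
    p = np.clip(sites["p"].to_numpy(dtype=float), _P_LO, _P_HI)
    z = norm.isf(p)

    out = np.empty(len(p))
    # cumulative sums within chromosome blocks; neighbours found by searchsorted
    start = 0
    for _, block in sites.groupby("chrom", sort=False):
        n = len(block)
        bpos = pos[start:start + n]
        bz = z[start:start + n]
        cz = np.concatenate([[0.0], np.cumsum(bz)])
        lo = np.searchsorted(bpos, bpos - distance, side="left")
        hi = np.searchsorted(bpos, bpos + distance, side="right")
        k = hi - lo
        zstar = (cz[hi] - cz[lo]) / np.sqrt(k)
        adj = norm.sf(zstar)
        # k = 1 must be the exact identity, not a round-trip through Phi
        adj[k == 1] = p[start:start + n][k == 1]
        out[start:start + n] = adj
        start += n
    return out


def merge_dmrs(
    sites: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Merge significant neighbouring sites into DMRs.

    ``sites`` needs chrom, pos, delta and ``p_adj`` (neighbour-combined p),
    sorted by (chrom, pos). The neighbour-combined p-values are
    Benjamini-Hochberg adjusted across all sites first — without multiplicity
    control a genome-scale scan emits runs of chance-significant sites at a
    high rate. Runs are then maximal stretches of sites with adjusted
    ``p_adj`` q-value < alpha, consecutive gaps <= neighbor_distance, and one
    delta sign. A run is reported iff it has >= min_dmr_dmcs member sites
    with |delta| >= min_delta and |mean delta| >= min_delta.

    Returns a region table: chrom, start, end (first to last CpG + 1), n_cpgs,
    n_sig_cpgs, mean_delta, p_region (min member corrected p), kind="DMR",
    and member_rows (index lists into ``sites``) for self-audit.
    """
    config = config or PipelineConfig()
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    delta = sites["delta"].to_numpy(dtype=float)
    padj = bh_adjust(sites["p_adj"].to_numpy(dtype=float))

    sig = padj < config.alpha
    sign = np.sign(delta)
    regions = []
    run: list[int] = []

    def flush(run: list[int]) -> None:
        if not run:
            return
        d = delta[run]
        n_sig = int((np.abs(d) >= config.min_delta).sum())
        mean_d = float(d.mean())
        p_region = float(padj[run].min())
        if n_sig >= config.min_dmr_dmcs and abs(mean_d) >= config.min_delta and p_region < config.alpha:
            regions.append(
                {
                    "chrom": chrom[run[0]],
                    "start": int(pos[run[0]]),
                    "end": int(pos[run[-1]]) + 1,
                    "n_cpgs": len(run),
                    "n_sig_cpgs": n_sig,
                    "mean_delta": mean_d,
                    "p_region": p_region,
                    "kind": "DMR",
                    "member_rows": list(run),
                }
            )

    for i in range(len(sites)):
        if not sig[i] or sign[i] == 0:
            flush(run)
            run = []
            continue
        if run and (
            chrom[i] != chrom[run[-1]]
            or pos[i] - pos[run[-1]] > config.neighbor_distance
            or sign[i] != sign[run[-1]]
        ):
            flush(run)
            run = []
        run.append(i)
    flush(run)
    cols = ["chrom", "start", "end", "n_cpgs", "n_sig_cpgs", "mean_delta", "p_region", "kind", "member_rows"]
    return pd.DataFrame(regions, columns=cols)


def annotate_region_promoters(
    regions: pd.DataFrame, genes: list[GeneModel], promoter_bp: int = 1000
) -> pd.DataFrame:
    """Intersect regions with strand-aware promoter windows and gene bodies.

    The promoter of a gene is the ``promoter_bp`` window immediately upstream
    of its transcription start: ``[TSS - promoter_bp, TSS)`` on the plus
    strand, ``[tx_end, tx_end + promoter_bp)`` on the minus strand. Returns
    one row per (region, gene) hit with hit_type in {promoter, gene_body}; a
    region overlapping both windows of one gene yields the promoter row only.
    """
    hits = []
    for idx, r in regions.iterrows():
        for g in genes:
            if g.chrom != r["chrom"]:
                continue
            ps, pe = g.promoter(promoter_bp)
            if r["start"] < pe and ps < r["end"]:
                hits.append({"region": idx, "gene_id": g.gene_id, "hit_type": "promoter"})
            elif r["start"] < g.tx_end and g.tx_start < r["end"]:
                hits.append({"region": idx, "gene_id": g.gene_id, "hit_type": "gene_body"})
    return pd.DataFrame(hits, columns=["region", "gene_id", "hit_type"])
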