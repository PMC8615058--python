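"""Genomic annotation of CpG sites and regions.

Sites/regions get exactly one functional class by precedence
(promoter > 5'UTR > 3'UTR > exonic > intronic > intergenic) and one CpG-island
context (island, shore = within 2 kb of an island edge, shelf = 2-4 kb,
inter otherwise). Gene-set utilities intersect DMC-bearing genes with curated
sets (e.g. hearing-loss, sporadic-disease and stria vascularis panels) and
summarise per-CpG methylation of a set's genes by sample group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel
from .preprocess import RatioMatrix

__all__ = [
    "GeneSet",
    "classify_functional",
    "classify_cpg_context",
    "intersect_gene_sets",
    "geneset_mean_methylation",
]

FUNCTIONAL_PRECEDENCE = ("promoter", "utr5", "utr3", "exonic", "intronic", "intergenic")

SHORE_BP = 2000
SHELF_BP = 4000

# published sizes of the curated inner-ear panels this analysis is normally
# run with; the gene lists themselves are user-supplied flat files
KNOWN_SET_SIZES = {"HL": 224, "SMD": 70, "SV": 217}


@dataclass
class GeneSet:
    """A named panel of gene symbols (uppercase-normalised, non-empty)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    @classmethod
    def from_file(cls, name: str, path: str | Path) -> "GeneSet":
        """Load one symbol per line (``#`` comments ignored).

        For the known panels (see ``KNOWN_SET_SIZES``) the loaded size is not
        enforced — panels are revised over time — but callers can compare.
        """
        genes = {ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip() and not ln.startswith("#")}
        return cls(name=name, genes=frozenset(genes))


def _overlaps(qs: int, qe: int, ivs: list[tuple[int, int]]) -> bool:
    return any(qs < e and s < qe for s, e in ivs)


def classify_functional(
    queries: pd.DataFrame, genes: list[GeneModel], promoter_bp: int = 1000
) -> pd.DataFrame:
    """Assign one functional class per site/region plus the gene ids hit.

    ``queries`` needs chrom plus either pos (a 1-bp site) or start/end.
    A query touching several genes takes the highest-precedence class over
    all of them; every overlapped gene id is kept in ``gene_ids``
    (comma-joined, promoter hits included).
    """
    df = queries.copy()
    if "start" not in df.columns:
        df["start"] = df["pos"]
        df["end"] = df["pos"] + 1
    qs = df["start"].to_numpy()
    qe = df["end"].to_numpy()
    qchrom = df["chrom"].to_numpy()

    rank = {c: i for i, c in enumerate(FUNCTIONAL_PRECEDENCE)}
    best = np.full(len(df), rank["intergenic"], dtype=int)
    gene_hits: list[set[str]] = [set() for _ in range(len(df))]

    for g in genes:
        on = qchrom == g.chrom
        if not on.any():
            continue
        ps, pe = g.promoter(promoter_bp)
        for i in np.flatnonzero(on):
            s, e = int(qs[i]), int(qe[i])
            cls = None
            if s < pe and ps < e:
                cls = "promoter"
            if s < g.tx_end and g.tx_start < e:
                if cls is None:
                    if _overlaps(s, e, g.utr5):
                        cls = "utr5"
                    elif _overlaps(s, e, g.utr3):
                        cls = "utr3"
                    elif _overlaps(s, e, g.exons):
                        cls = "exonic"
                    else:
                        cls = "intronic"
                gene_hits[i].add(g.gene_id)
            elif cls == "promoter":
                gene_hits[i].add(g.gene_id)
            if cls is not None and rank[cls] < best[i]:
                best[i] = rank[cls]

    df["functional_class"] = [FUNCTIONAL_PRECEDENCE[b] for b in best]
    df["gene_ids"] = [",".join(sorted(h)) for h in gene_hits]
    return df


def classify_cpg_context(sites: pd.DataFrame, islands: pd.DataFrame) -> pd.Series:
    """CpG-island context per site: island / shore / shelf / inter.

    ``islands`` holds merged, sorted 0-based half-open intervals. A site
    inside an island is ``island``; within 2 kb beyond an edge, ``shore``
    (half-open, so exactly 2 kb away is already ``shelf``); within 2-4 kb,
    ``shelf``; farther, ``inter``.
    """
    out = np.full(len(sites), "inter", dtype=object)
    pos_all = sites["pos"].to_numpy()
    chrom_all = sites["chrom"].to_numpy()
    for chrom, block in islands.groupby("chrom", sort=False):
        on = np.flatnonzero(chrom_all == chrom)
        if len(on) == 0:
            continue
        pos = pos_all[on]
        starts = block["start"].to_numpy()
        ends = block["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        # distance beyond the nearest island edge (0 = first base outside)
        d_prev = np.where(idx >= 0, pos - ends[np.clip(idx, 0, None)], np.inf)
        nxt = np.clip(idx + 1, None, len(starts) - 1)
        d_next = np.where(idx + 1 < len(starts), starts[nxt] - pos - 1, np.inf)
        dist = np.minimum(d_prev, d_next)
        ctx = np.where(inside, "island", np.where(dist < SHORE_BP, "shore", np.where(dist < SHELF_BP, "shelf", "inter")))
        out[on] = ctx
    return pd.Series(out, index=sites.index, name="cpg_context")


def intersect_gene_sets(dmc_genes: set[str], gene_sets: list[GeneSet]) -> dict:
    """Per-set DMC gene counts and the Venn partition across sets.

    Returns ``{"per_set": {name: {"n_genes": ...}}, "venn": {membership
    pattern like "HL&SV": sorted gene list}}`` over DMC-bearing genes.
    """
    dmc_genes = {g.upper() for g in dmc_genes}
    per_set = {}
    for gs in gene_sets:
        hit = dmc_genes & gs.genes
        per_set[gs.name] = {"n_genes": len(hit), "genes": sorted(hit)}
    venn: dict[str, list[str]] = {}
    union = set().union(*(dmc_genes & gs.genes for gs in gene_sets)) if gene_sets else set()
    for g in union:
        key = "&".join(gs.name for gs in gene_sets if g in gs.genes)
        venn.setdefault(key, []).append(g)
    return {"per_set": per_set, "venn": {k: sorted(v) for k, v in venn.items()}}


def genes_for_sites(sites: pd.DataFrame, genes: list[GeneModel], promoter_bp: int = 1000) -> pd.Series:
    """Comma-joined gene ids (body or promoter) per site."""
    return classify_functional(sites, genes, promoter_bp)["gene_ids"]


def geneset_mean_methylation(
    ratios: RatioMatrix,
    gene_set: GeneSet,
    genes: list[GeneModel],
    promoter_bp: int = 1000,
    comparisons: tuple[tuple[str, ...], ...] = (("MDH", "MDL"), ("MDH",), ("MDL",)),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-CpG group means over a gene set's genes plus pairwise group tests.

    A CpG maps to the set when it falls in the body or promoter window of a
    set gene. Returns (per-CpG mean table with one column per group label
    pattern, pairwise t-test table). Comparisons are each case pool against
    controls plus case pool vs case pool.
    """
    set_models = [g for g in genes if g.gene_id.upper() in gene_set.genes]
    mask = np.zeros(ratios.n_sites, dtype=bool)
    pos = ratios.sites["pos"].to_numpy()
    chrom = ratios.sites["chrom"].to_numpy()
    for g in set_models:
        ps, pe = g.promoter(promoter_bp)
        lo, hi = min(ps, g.tx_start), max(pe, g.tx_end)
        mask |= (chrom == g.chrom) & (pos >= lo) & (pos < hi)
    if not mask.any():
        raise ValueError(f"no CpGs map to gene set {gene_set.name!r}")

    sub = ratios.subset_sites(mask)
    pools: dict[str, np.ndarray] = {"control": sub.group_columns("control").mean(axis=1)}
    labels = {"control": "control"}
    for comp in comparisons:
        name = "MD" if set(comp) == {"MDH", "MDL"} else comp[0]
        pools[name] = sub.group_columns(comp).mean(axis=1)
        labels[name] = name
    table = sub.sites.copy()
    for name, vals in pools.items():
        table[f"mean_{name}"] = vals

    tests = []
    pairs = [(n, "control") for n in pools if n != "control"]
    if "MDH" in pools and "MDL" in pools:
        pairs.append(("MDH", "MDL"))
    for a, b in pairs:
        x, y = pools[a], pools[b]
        if np.array_equal(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(x, y)
        tests.append({"group_a": a, "group_b": b, "mean_a": float(np.mean(x)), "mean_b": float(np.mean(y)), "t": float(t), "p": float(p)})
    return table, pd.DataFrame(tests)
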