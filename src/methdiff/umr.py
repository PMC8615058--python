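"""Per-sample undermethylated region (UMR) analysis.

Each sample's methylome (sites at >= 10X coverage for that sample) is first
screened for partially methylated domains (PMDs) — long blocks of
intermediate methylation that would otherwise flood the UMR caller — which
are masked out. UMR candidates are then maximal runs of at least four
consecutive CpGs that each sit below a per-site ceiling (0.30) with a run
average below 0.10; candidates are kept at an empirical FDR of 5% estimated
by permuting per-site ratios across the genome. Finally, regions observed in
more than 75% of case samples and in no control sample are reported as
case-exclusive consensus UMRs via an atomic-interval (multi-intersection)
partition of the genome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import PipelineConfig

__all__ = ["detect_pmds", "segment_umrs", "exclusive_umrs", "sample_site_table"]


def sample_site_table(matrix, sample: str, min_coverage: int = 10) -> pd.DataFrame:
    """One sample's (chrom, pos, ratio) at the per-sample coverage floor."""
    j = matrix.samples.index(sample)
    keep = matrix.total[:, j] >= min_coverage
    out = matrix.sites[keep].reset_index(drop=True).copy()
    out["ratio"] = matrix.meth[keep, j] / matrix.total[keep, j]
    return out


def detect_pmds(sites: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Find partially methylated domains in one sample.

    A two-state segmentation on the rolling median methylation: CpGs whose
    centred ``pmd_window_cpgs``-wide window median falls in ``pmd_band``
    (default [0.10, 0.60]) are in the PMD state, and maximal PMD-state runs of
    at least ``pmd_min_cpgs`` CpGs are reported. The median, not the mean, is
    deliberate: a PMD is a domain whose *individual* CpGs sit at intermediate
    methylation, whereas a fully unmethylated region (UMR, CpG island)
    embedded in high background produces a bimodal window whose mean — but
    not median — drifts into the PMD band. Windows are computed within one
    chromosome; partial windows at chromosome edges are left in the
    background state.

    Returns a table chrom, start, end, n_cpgs, mean_meth, kind="PMD".
    """
    config = config or PipelineConfig()
    lo, hi = config.pmd_band
    out = []
    for chrom, block in sites.groupby("chrom", sort=False):
        pos = block["pos"].to_numpy()
        r = block["ratio"].to_numpy(dtype=float)
        roll = pd.Series(r).rolling(config.pmd_window_cpgs, center=True, min_periods=config.pmd_window_cpgs).median().to_numpy()
        in_band = (roll >= lo) & (roll <= hi)
        for a, b in _runs(in_band):
            if b - a >= config.pmd_min_cpgs:
                out.append(
                    {
                        "chrom": chrom,
                        "start": int(pos[a]),
                        "end": int(pos[b - 1]) + 1,
                        "n_cpgs": int(b - a),
                        "mean_meth": float(r[a:b].mean()),
                        "kind": "PMD",
                    }
                )
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_cpgs", "mean_meth", "kind"])


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs."""
    if len(mask) == 0:
        return
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[~mask[edges]] + 1)
    stops = list(edges[mask[edges]] + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        stops = stops + [len(mask)]
    yield from zip(starts, stops)


def _candidates(chrom: np.ndarray, pos: np.ndarray, ratio: np.ndarray, config: PipelineConfig) -> list[dict]:
    """Maximal low-methylation runs meeting length and average criteria."""
    cands = []
    low = ratio < config.umr_site_max_meth
    # break runs at chromosome changes
    brk = np.zeros(len(chrom), dtype=bool)
    brk[1:] = chrom[1:] != chrom[:-1]
    for a, b in _runs(low):
        # split at chromosome boundaries inside the run
        cuts = [a] + [i for i in range(a + 1, b) if brk[i]] + [b]
        for s, e in zip(cuts[:-1], cuts[1:]):
            n = e - s
            if n < config.umr_min_cpgs:
                continue
            avg = float(ratio[s:e].mean())
            if avg >= config.umr_max_meth:
                continue
            cands.append(
                {
                    "chrom": chrom[s],
                    "start": int(pos[s]),
                    "end": int(pos[e - 1]) + 1,
                    "n_cpgs": int(n),
                    "mean_meth": avg,
                    "kind": "UMR",
                }
            )
    return cands


def segment_umrs(
    sites: pd.DataFrame,
    config: PipelineConfig | None = None,
    pmds: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Call one sample's UMRs with an empirical permutation FDR.

    ``sites`` is the sample's coverage-filtered (chrom, pos, ratio) table.
    Sites inside ``pmds`` intervals are masked first. Candidate regions are
    scored by CpG count; the null score distribution comes from
    ``config.umr_permutations`` genome-wide permutations of the ratio column,
    and candidates are kept above the smallest score whose estimated FDR
    (mean null count at or above the score over the observed count) is at
    most ``config.umr_fdr``.
    """
    config = config or PipelineConfig()
    rng = rng or np.random.default_rng(config.seed)
    if pmds is not None and len(pmds):
        masked = np.zeros(len(sites), dtype=bool)
        for chrom, start, end in pmds[["chrom", "start", "end"]].itertuples(index=False):
            masked |= (sites["chrom"] == chrom).to_numpy() & (sites["pos"].to_numpy() >= start) & (
                sites["pos"].to_numpy() < end
            )
        sites = sites[~masked].reset_index(drop=True)
    if len(sites) < config.umr_min_cpgs:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs", "mean_meth", "kind"])

    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    ratio = sites["ratio"].to_numpy(dtype=float)
    obs = _candidates(chrom, pos, ratio, config)
    if not obs:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs", "mean_meth", "kind"])
    obs_scores = np.array([c["n_cpgs"] for c in obs])

    null_scores = []
    for _ in range(config.umr_permutations):
        perm = rng.permutation(ratio)
        null_scores.extend(c["n_cpgs"] for c in _candidates(chrom, pos, perm, config))
    null_scores = np.array(null_scores, dtype=float)

    threshold = np.inf
    for s in np.sort(np.unique(obs_scores)):
        n_obs = (obs_scores >= s).sum()
        n_null = (null_scores >= s).sum() / config.umr_permutations
        if n_null / n_obs <= config.umr_fdr:
            threshold = s
            break
    kept = [c for c, sc in zip(obs, obs_scores) if sc >= threshold]
    return pd.DataFrame(kept, columns=["chrom", "start", "end", "n_cpgs", "mean_meth", "kind"])


def exclusive_umrs(
    case_sets: dict[str, pd.DataFrame],
    control_sets: dict[str, pd.DataFrame],
    fraction: float = 0.75,
) -> pd.DataFrame:
    """Consensus regions carried by a strict majority of cases and no control.

    The genome is partitioned into atomic intervals by every region boundary
    across all samples (multi-intersection semantics: a 1-bp overlap counts).
    An atomic interval is kept when strictly more than ``fraction`` of the
    case samples have a UMR covering it and no control sample does; adjacent
    kept intervals are merged. Returns chrom, start, end, n_case_samples.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if not case_sets:
        raise ValueError("need at least one case sample")
    n_cases = len(case_sets)
    need = fraction * n_cases

    pieces = []
    for sample, df in case_sets.items():
        if len(df):
            pieces.append(df[["chrom", "start", "end"]].assign(sample=sample, is_case=True))
    for sample, df in control_sets.items():
        if len(df):
            pieces.append(df[["chrom", "start", "end"]].assign(sample=sample, is_case=False))
    if not pieces:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_case_samples"])
    allr = pd.concat(pieces, ignore_index=True)

    kept = []
    for chrom, block in allr.groupby("chrom", sort=True):
        bounds = np.unique(np.concatenate([block["start"].to_numpy(), block["end"].to_numpy()]))
        starts, ends = bounds[:-1], bounds[1:]
        case_cov = np.zeros(len(starts), dtype=int)
        ctrl_cov = np.zeros(len(starts), dtype=int)
        for (sample, is_case), sub in block.groupby(["sample", "is_case"], sort=False):
            covered = np.zeros(len(starts), dtype=bool)
            for s, e in sub[["start", "end"]].itertuples(index=False):
                i, j = np.searchsorted(bounds, s), np.searchsorted(bounds, e)
                covered[i:j] = True
            if is_case:
                case_cov += covered
            else:
                ctrl_cov += covered
        ok = (case_cov > need) & (ctrl_cov == 0)
        current = None
        for i in np.flatnonzero(ok):
            if current is not None and current["end"] == starts[i]:
                current["end"] = int(ends[i])
                current["n_case_samples"] = min(current["n_case_samples"], int(case_cov[i]))
            else:
                if current is not None:
                    kept.append(current)
                current = {
                    "chrom": chrom,
                    "start": int(starts[i]),
                    "end": int(ends[i]),
                    "n_case_samples": int(case_cov[i]),
                }
        if current is not None:
            kept.append(current)
    return pd.DataFrame(kept, columns=["chrom", "start", "end", "n_case_samples"])
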