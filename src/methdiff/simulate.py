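"""Synthetic WGBS cohort generator with machine-readable ground truth.

Emulates the statistical structure of a small case-control bisulfite cohort:
~15X negative-binomial coverage, bimodal baseline methylation (CpG islands low
~Beta(1,19), background high ~Beta(18,2)), 6 controls vs 7+7 cases in two
cytokine-defined case subgroups, batch-by-origin logit offsets, planted
differentially methylated CpGs and clustered regions with |delta| >= 0.08,
and case-exclusive undermethylated blocks carried by ~80% of cases.

The generator writes the same Bismark-style coverage dialect the readers
accept, plus a sample sheet, gene models, a CpG-island track and a truth
object for recovery scoring. All randomness flows from one seed; output is
byte-identical across reruns.

Coverage model: total reads per (site, sample) are negative binomial with
mean ``coverage_mean`` and dispersion ``coverage_dispersion`` defined as the
relative variance excess over Poisson (variance = mu * (1 + dispersion)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GeneModel, write_coverage_file, write_gene_table

__all__ = ["SimConfig", "SyntheticTruth", "SyntheticCohort", "generate_cohort", "score_recovery"]


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    seed: int = 0
    n_chroms: int = 2
    chrom_size: int = 1_000_000
    n_sites: int = 20_000
    n_genes: int = 40
    n_islands: int = 60
    n_controls: int = 6
    n_mdh: int = 7
    n_mdl: int = 7
    coverage_mean: float = 15.0
    coverage_dispersion: float = 0.3
    island_beta: tuple[float, float] = (1.0, 19.0)
    background_beta: tuple[float, float] = (18.0, 2.0)
    n_dmcs: int = 200
    dmc_delta: float = 0.30
    dmc_hypo_fraction: float = 0.7
    n_dmrs: int = 10
    dmr_cpgs: int = 10
    dmr_delta: float = 0.25
    n_umrs: int = 12
    umr_cpgs: int = 20
    umr_carrier_fraction: float = 0.8
    umr_level: float = 0.02
    n_batches: int = 2
    batch_logit_offsets: tuple[float, ...] = (0.0, 0.3)
    noise_sd: float = 0.03
    ratio_clip: tuple[float, float] = (0.001, 0.999)

    def __post_init__(self) -> None:
        if not (0 < self.umr_carrier_fraction <= 1):
            raise ValueError("umr_carrier_fraction must be in (0, 1]")
        if self.dmc_delta < 0.08 or self.dmr_delta < 0.08:
            raise ValueError("planted |delta| must be >= 0.08")
        if len(self.batch_logit_offsets) != self.n_batches:
            raise ValueError("one logit offset per batch required")


@dataclass
class SyntheticTruth:
    """Planted-feature coordinates and effects for recovery scoring.

    ``dmc`` lists every site with a planted group difference (standalone
    DMCs, DMR cluster members, and UMR block sites, distinguished by
    ``source``); ``dmr`` and ``umr`` are interval tables; ``umr`` carries the
    carrier sample ids per block. ``genes_with_dmc`` are genes whose body or
    promoter holds a planted differential site.
    """

    dmc: pd.DataFrame
    dmr: pd.DataFrame
    umr: pd.DataFrame
    batch_offsets: dict[str, float]
    genes_with_dmc: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        d = {
            "dmc": self.dmc.to_dict(orient="list"),
            "dmr": self.dmr.to_dict(orient="list"),
            "umr": self.umr.assign(carriers=self.umr["carriers"].map(",".join)).to_dict(orient="list"),
            "batch_offsets": self.batch_offsets,
            "genes_with_dmc": self.genes_with_dmc,
        }
        Path(path).write_text(json.dumps(d, indent=1))


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort: per-sample count tables plus metadata."""

    tables: dict[str, pd.DataFrame]
    sheet: pd.DataFrame
    truth: SyntheticTruth
    genes: list[GeneModel]
    islands: pd.DataFrame
    config: SimConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, df in self.tables.items():
            write_coverage_file(df, outdir / f"{sample}.cov", dialect="bismark_cov")
        self.sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        self.islands.to_csv(outdir / "cpg_islands.bed", sep="\t", index=False, header=False)
        write_gene_table(self.genes, outdir / "genes.tsv")
        self.truth.to_json(outdir / "truth.json")
        cfg = asdict(self.config)
        for k, v in cfg.items():
            if isinstance(v, tuple):
                cfg[k] = list(v)
        (outdir / "sim_config.json").write_text(json.dumps(cfg, indent=1))


def _place_islands(rng, cfg: SimConfig) -> pd.DataFrame:
    rows = []
    per_chrom = cfg.n_islands // cfg.n_chroms
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        slot = cfg.chrom_size // per_chrom
        for i in range(per_chrom):
            length = int(rng.integers(600, 1400))
            start = i * slot + int(rng.integers(0, max(1, slot - length - 1)))
            rows.append((chrom, start, start + length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _place_sites(rng, cfg: SimConfig, islands: pd.DataFrame) -> pd.DataFrame:
    """CpG positions: dense inside islands (~9% of sites), uniform outside."""
    frames = []
    per_island = max(4, int(round(0.09 * cfg.n_sites / max(len(islands), 1))))
    n_bg_per_chrom = (cfg.n_sites - per_island * len(islands)) // cfg.n_chroms
    if n_bg_per_chrom <= 0:
        raise ValueError("n_sites too small for the island layout")
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        isl = islands[islands["chrom"] == chrom]
        pos_list = []
        for s, e in isl[["start", "end"]].itertuples(index=False):
            pos_list.append(rng.choice(np.arange(s, e, 2), size=min(per_island, (e - s) // 2), replace=False))
        bg = rng.choice(np.arange(0, cfg.chrom_size, 2), size=n_bg_per_chrom, replace=False)
        inside = np.zeros(len(bg), dtype=bool)
        for s, e in isl[["start", "end"]].itertuples(index=False):
            inside |= (bg >= s) & (bg < e)
        pos_list.append(bg[~inside])
        pos = np.unique(np.concatenate(pos_list))
        pos = pos[np.concatenate([[True], np.diff(pos) >= 2])]
        in_island = np.zeros(len(pos), dtype=bool)
        for s, e in isl[["start", "end"]].itertuples(index=False):
            in_island |= (pos >= s) & (pos < e)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "is_island": in_island}))
    return pd.concat(frames, ignore_index=True)


def _place_genes(rng, cfg: SimConfig) -> list[GeneModel]:
    genes = []
    per_chrom = cfg.n_genes // cfg.n_chroms
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        slot = cfg.chrom_size // per_chrom
        for i in range(per_chrom):
            length = int(rng.integers(10_000, 40_000))
            start = i * slot + int(rng.integers(2000, max(2001, slot - length - 1)))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(3, 6))
            cuts = np.sort(rng.choice(np.arange(start, end, 100), size=2 * n_ex, replace=False))
            exons = [(int(cuts[2 * j]), int(cuts[2 * j + 1])) for j in range(n_ex) if cuts[2 * j] < cuts[2 * j + 1]]
            if not exons:
                exons = [(start, start + 200)]
            first, last = exons[0], exons[-1]
            if strand == "+":
                utr5 = [(first[0], min(first[1], first[0] + 100))]
                utr3 = [(max(last[0], last[1] - 100), last[1])]
            else:
                utr5 = [(max(last[0], last[1] - 100), last[1])]
                utr3 = [(first[0], min(first[1], first[0] + 100))]
            genes.append(
                GeneModel(
                    gene_id=f"GENE{c * per_chrom + i + 1:03d}",
                    chrom=chrom, strand=strand, tx_start=start, tx_end=end,
                    exons=exons, utr5=utr5, utr3=utr3,
                )
            )
    return genes


def _pick_runs(rng, eligible_start: np.ndarray, run_len: int, n_runs: int, reserved: np.ndarray, buffer: int = 3) -> list[int]:
    """Choose non-overlapping run start indices among eligible positions."""
    starts: list[int] = []
    candidates = rng.permutation(np.flatnonzero(eligible_start))
    for i in candidates:
        if len(starts) == n_runs:
            break
        lo, hi = max(0, i - buffer), i + run_len + buffer
        if reserved[lo:hi].any():
            continue
        reserved[lo:hi] = True
        starts.append(int(i))
    if len(starts) < n_runs:
        raise ValueError("could not place all planted features; genome too small or too crowded")
    return starts


def generate_cohort(config: SimConfig | None = None, coverage_override: float | None = None) -> SyntheticCohort:
    """Simulate the cohort and its ground truth.

    Per (site, sample): true ratio = clip(baseline + planted effect + noise),
    shifted on the logit scale by the sample's batch offset; total reads are
    negative binomial; methylated reads are binomial(total, true ratio).
    ``coverage_override`` replaces the negative-binomial mean with a fixed
    high coverage (diagnostics and law-of-large-numbers checks).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    islands = _place_islands(rng, cfg)
    sites = _place_sites(rng, cfg, islands).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    genes = _place_genes(rng, cfg)
    n = len(sites)
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    is_island = sites["is_island"].to_numpy()

    # samples, groups, batches (origins balanced within each group)
    samples, groups = [], []
    for prefix, count, label in (("CTRL", cfg.n_controls, "control"), ("MDH", cfg.n_mdh, "MDH"), ("MDL", cfg.n_mdl, "MDL")):
        for i in range(count):
            samples.append(f"{prefix}{i + 1}")
            groups.append(label)
    batch_names = [f"origin{i + 1}" for i in range(cfg.n_batches)]
    batches = []
    for label in ("control", "MDH", "MDL"):
        members = [i for i, g in enumerate(groups) if g == label]
        for j, _ in enumerate(members):
            batches.append(batch_names[j % cfg.n_batches])
    sheet = pd.DataFrame({"sample": samples, "group": groups, "batch": batches})
    is_case = np.array([g != "control" for g in groups])
    cases = [s for s, c in zip(samples, is_case) if c]

    # baseline methylation, bimodal by island membership
    baseline = np.where(
        is_island,
        rng.beta(*cfg.island_beta, size=n),
        rng.beta(*cfg.background_beta, size=n),
    )

    # ---- feature placement ----
    reserved = np.zeros(n, dtype=bool)
    same_chrom_run = lambda L: np.array(
        [i + L <= n and chrom[i] == chrom[i + L - 1] for i in range(n)], dtype=bool
    )

    # UMR blocks: runs of background sites, buffered away from islands
    bg_run = same_chrom_run(cfg.umr_cpgs)
    for k in range(cfg.umr_cpgs):
        bg_run[: n - k] &= ~is_island[k:] if k else ~is_island
    # also require the immediate index-neighbours to be background
    pad = np.ones(n, dtype=bool)
    pad[1:] &= ~is_island[:-1]
    pad[: n - cfg.umr_cpgs] &= ~np.roll(is_island, -cfg.umr_cpgs)[: n - cfg.umr_cpgs]
    umr_starts = _pick_runs(rng, bg_run & pad, cfg.umr_cpgs, cfg.n_umrs, reserved)

    # DMR clusters: background runs with all internal gaps <= 200 bp
    dmr_run = same_chrom_run(cfg.dmr_cpgs)
    for k in range(cfg.dmr_cpgs):
        dmr_run[: n - k] &= ~is_island[k:] if k else ~is_island
    gaps_ok = np.ones(n, dtype=bool)
    d = np.diff(pos)
    same = chrom[1:] == chrom[:-1]
    gap_small = np.concatenate([same & (d <= 200), [False]])
    for k in range(cfg.dmr_cpgs - 1):
        gaps_ok[: n - k] &= gap_small[k:] if k else gap_small
    dmr_starts = _pick_runs(rng, dmr_run & gaps_ok, cfg.dmr_cpgs, cfg.n_dmrs, reserved)

    # standalone DMCs: hypo on background, hyper inside islands
    n_hypo = int(round(cfg.n_dmcs * cfg.dmc_hypo_fraction))
    hypo_idx = _pick_runs(rng, ~is_island & ~reserved, 1, n_hypo, reserved, buffer=2)
    hyper_idx = _pick_runs(rng, is_island & ~reserved, 1, cfg.n_dmcs - n_hypo, reserved, buffer=2)

    # ---- planted effect per site (case samples) ----
    delta = np.zeros(n)
    source = np.full(n, "", dtype=object)
    for i in hypo_idx:
        delta[i], source[i] = -cfg.dmc_delta, "dmc"
    for i in hyper_idx:
        delta[i], source[i] = cfg.dmc_delta, "dmc"
    dmr_rows = []
    for s in dmr_starts:
        sl = slice(s, s + cfg.dmr_cpgs)
        delta[sl], source[sl] = -cfg.dmr_delta, "dmr"
        dmr_rows.append(
            {"chrom": chrom[s], "start": int(pos[s]), "end": int(pos[s + cfg.dmr_cpgs - 1]) + 1,
             "n_cpgs": cfg.dmr_cpgs, "delta": -cfg.dmr_delta}
        )

    # UMR carriers: ceil(fraction * n_cases) case samples per block, no controls
    n_carriers = int(np.ceil(cfg.umr_carrier_fraction * len(cases)))
    umr_rows = []
    umr_member = np.zeros((n, len(samples)), dtype=bool)
    sample_col = {s: j for j, s in enumerate(samples)}
    for s in umr_starts:
        carriers = sorted(rng.choice(cases, size=n_carriers, replace=False))
        sl = slice(s, s + cfg.umr_cpgs)
        source[sl] = "umr"
        for csample in carriers:
            umr_member[sl, sample_col[csample]] = True
        umr_rows.append(
            {"chrom": chrom[s], "start": int(pos[s]), "end": int(pos[s + cfg.umr_cpgs - 1]) + 1,
             "n_cpgs": cfg.umr_cpgs, "carriers": carriers}
        )

    # ---- per-sample true ratios, coverage, counts ----
    lo, hi = cfg.ratio_clip
    offsets = dict(zip(batch_names, cfg.batch_logit_offsets))
    tables: dict[str, pd.DataFrame] = {}
    r_nb = cfg.coverage_mean / cfg.coverage_dispersion  # variance = mu (1 + dispersion)
    p_nb = r_nb / (r_nb + cfg.coverage_mean)
    for j, sample in enumerate(samples):
        true = baseline.copy()
        if is_case[j]:
            true = true + delta
        block = umr_member[:, j]
        true[block] = cfg.umr_level
        true = true + rng.normal(0.0, cfg.noise_sd, size=n)
        true = np.clip(true, lo, hi)
        off = offsets[batches[j]]
        if off != 0.0:
            true = 1.0 / (1.0 + np.exp(-(np.log(true / (1 - true)) + off)))
            true = np.clip(true, lo, hi)
        if coverage_override is not None:
            total = np.full(n, int(coverage_override))
        else:
            total = rng.negative_binomial(r_nb, p_nb, size=n)
        meth = rng.binomial(total, true)
        keep = total > 0
        tables[sample] = pd.DataFrame(
            {"chrom": chrom[keep], "pos": pos[keep], "meth": meth[keep], "total": total[keep]}
        )

    # ---- truth ----
    carrier_share = n_carriers / len(cases)
    truth_delta = delta.copy()
    umr_any = umr_member.any(axis=1)
    truth_delta[umr_any] = carrier_share * (cfg.umr_level - baseline[umr_any])
    planted = source != ""
    dmc_truth = pd.DataFrame(
        {
            "chrom": chrom[planted],
            "pos": pos[planted],
            "delta": truth_delta[planted],
            "direction": np.where(truth_delta[planted] < 0, "hypo", "hyper"),
            "source": source[planted],
        }
    )
    genes_with_dmc = sorted(
        {
            g.gene_id
            for g in genes
            for c, p in zip(chrom[planted], pos[planted])
            if g.chrom == c and (g.promoter()[0] <= p < g.promoter()[1] or g.tx_start <= p < g.tx_end)
        }
    )
    dmr_truth = pd.DataFrame(dmr_rows, columns=["chrom", "start", "end", "n_cpgs", "delta"])
    umr_truth = pd.DataFrame(umr_rows, columns=["chrom", "start", "end", "n_cpgs", "carriers"])
    truth = SyntheticTruth(
        dmc=dmc_truth.sort_values(["chrom", "pos"]).reset_index(drop=True),
        dmr=dmr_truth.sort_values(["chrom", "start"]).reset_index(drop=True),
        umr=umr_truth.sort_values(["chrom", "start"]).reset_index(drop=True),
        batch_offsets=offsets,
        genes_with_dmc=genes_with_dmc,
    )
    return SyntheticCohort(
        tables=tables, sheet=sheet, truth=truth, genes=genes,
        islands=islands, config=cfg,
    )


def score_recovery(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    kind: str = "dmc",
    tested_sites: pd.DataFrame | None = None,
) -> dict:
    """Precision/recall/F1 of calls against planted truth.

    DMC matching is by exact (chrom, pos); region matching requires
    reciprocal 50% overlap (boundary inclusive). When ``tested_sites`` is
    given for DMCs, recall is computed over truth sites the pipeline actually
    tested (sites lost to the coverage filters cannot be recovered by any
    caller); the unrestricted recall is reported as ``recall_all``.
    With no calls, precision is reported as 1.0 with ``zero_calls`` set.
    """
    if len(truth) == 0:
        raise ValueError("empty truth")
    out: dict = {"kind": kind, "n_calls": int(len(calls)), "n_truth": int(len(truth))}
    if kind == "dmc":
        call_keys = set(zip(calls["chrom"], calls["pos"])) if len(calls) else set()
        truth_keys = set(zip(truth["chrom"], truth["pos"]))
        tp_all = len(call_keys & truth_keys)
        out["recall_all"] = tp_all / len(truth_keys)
        if tested_sites is not None:
            tested = set(zip(tested_sites["chrom"], tested_sites["pos"]))
            testable = truth_keys & tested
            out["n_truth_testable"] = len(testable)
            out["recall"] = (len(call_keys & testable) / len(testable)) if testable else 0.0
        else:
            out["recall"] = out["recall_all"]
        fp = len(call_keys - truth_keys)
        tp = tp_all
    else:
        matched_truth = 0
        matched_call = np.zeros(len(calls), dtype=bool)
        for _, t in truth.iterrows():
            tlen = t["end"] - t["start"]
            hit = False
            for ci, c in calls.iterrows():
                if c["chrom"] != t["chrom"]:
                    continue
                ov = min(c["end"], t["end"]) - max(c["start"], t["start"])
                clen = c["end"] - c["start"]
                if ov > 0 and ov >= 0.5 * tlen and ov >= 0.5 * clen:
                    hit = True
                    matched_call[calls.index.get_loc(ci)] = True
            if hit:
                matched_truth += 1
        out["recall"] = matched_truth / len(truth)
        tp = int(matched_call.sum())
        fp = int(len(calls) - tp)
    out["zero_calls"] = len(calls) == 0
    out["precision"] = 1.0 if len(calls) == 0 else tp / (tp + fp)
    pr, rc = out["precision"], out["recall"]
    out["f1"] = 0.0 if pr + rc == 0 else 2 * pr * rc / (pr + rc)
    return out
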