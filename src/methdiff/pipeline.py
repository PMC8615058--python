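"""End-to-end orchestration: filter -> ratios -> batch -> DMC -> DMR -> UMR ->
annotate -> enrich, with a run manifest for reproducibility.

The three analysis branches intentionally refilter from the assembled count
matrix with different coverage floors: DMC testing uses complete-case 10X
sites, region (DMR) calling uses complete-case 1X sites, and per-sample UMR
segmentation filters each sample independently at 10X.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import (
    GeneSet,
    classify_cpg_context,
    classify_functional,
    geneset_mean_methylation,
    intersect_gene_sets,
)
from .dmc import COMPARISONS, call_dmcs, chromosome_summary
from .dmr import annotate_region_promoters, combine_neighbor_pvalues, merge_dmrs
from .enrich import compute_bias, enrichment_table
from .io_formats import GeneModel, MethylomeMatrix, assemble_matrix, read_coverage_file, read_sample_sheet, write_bed
from .preprocess import PipelineConfig, compute_ratios, correct_batch, filter_sites
from .umr import detect_pmds, exclusive_umrs, sample_site_table, segment_umrs

__all__ = ["PipelineResult", "run_pipeline", "load_cohort_dir"]


@dataclass
class PipelineResult:
    matrix: MethylomeMatrix
    dmc_tables: dict[str, pd.DataFrame]
    dmr_tables: dict[str, pd.DataFrame]
    umr_by_sample: dict[str, pd.DataFrame]
    exclusive_umr: pd.DataFrame
    annotations: pd.DataFrame | None
    enrichment: dict[str, pd.DataFrame]
    manifest: dict
    log: list[str] = field(default_factory=list)
    gene_set_summary: dict | None = None


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def load_cohort_dir(indir: str | Path, dialect: str = "bismark_cov"):
    """Read a directory of per-sample coverage files plus samples.tsv."""
    indir = Path(indir)
    sheet = read_sample_sheet(indir / "samples.tsv")
    suffix = ".cov" if dialect == "bismark_cov" else ".tsv"
    tables = {}
    for s in sheet["sample"]:
        fp = indir / f"{s}{suffix}"
        if not fp.exists():
            raise FileNotFoundError(f"coverage file for sample {s} not found at {fp}")
        tables[s] = read_coverage_file(fp, dialect=dialect)
    return tables, sheet


def run_pipeline(
    tables: dict[str, pd.DataFrame],
    sheet: pd.DataFrame,
    config: PipelineConfig | None = None,
    comparisons: tuple[str, ...] = ("MD_vs_control",),
    genes: list[GeneModel] | None = None,
    islands: pd.DataFrame | None = None,
    gene_sets: list[GeneSet] | None = None,
    categories: dict[str, set[str]] | None = None,
    outdir: str | Path | None = None,
    input_paths: list[Path] | None = None,
) -> PipelineResult:
    """Run the full analysis on an assembled cohort.

    Any stage failure raises with the stage named. When ``outdir`` is given,
    stage outputs (TSV/BED) and the run manifest are written there.
    """
    config = config or PipelineConfig()
    unknown = set(comparisons) - set(COMPARISONS)
    if unknown:
        raise ValueError(f"unknown comparison(s) {sorted(unknown)}")
    log: list[str] = []
    counts: dict[str, int] = {}

    def stage(name):
        log.append(f"stage: {name}")

    stage("assemble")
    matrix = assemble_matrix(tables, sheet)
    counts["sites_assembled"] = matrix.n_sites

    # ---- DMC branch: complete-case 10X ----
    stage("filter")
    filtered = filter_sites(matrix, config, log=log)
    counts["sites_10x"] = filtered.n_sites
    dmc_tables: dict[str, pd.DataFrame] = {}
    if filtered.n_sites == 0:
        log.append("warning: no sites pass the 10X complete-case filter; DMC branch empty")
        ratios = None
    else:
        stage("ratios")
        ratios = compute_ratios(filtered)
        if config.batch_correct:
            stage("batch-correct")
            ratios = correct_batch(ratios, clip=config.logit_clip)
        stage("dmc")
        for comp in comparisons:
            dmc_tables[comp] = call_dmcs(ratios, comp, config)
            counts[f"dmc_{comp}"] = int(dmc_tables[comp]["significant"].sum())

    # ---- DMR branch: complete-case 1X ----
    stage("dmr")
    dmr_filtered = filter_sites(matrix, config, min_coverage=config.dmr_min_coverage, log=log)
    counts["sites_1x"] = dmr_filtered.n_sites
    dmr_tables: dict[str, pd.DataFrame] = {}
    if dmr_filtered.n_sites:
        dmr_ratios = compute_ratios(dmr_filtered)
        if config.batch_correct:
            dmr_ratios = correct_batch(dmr_ratios, clip=config.logit_clip)
        for comp in comparisons:
            site_table = call_dmcs(dmr_ratios, comp, config)
            site_table["p_adj"] = combine_neighbor_pvalues(site_table, distance=config.neighbor_distance)
            dmr_tables[comp] = merge_dmrs(site_table, config)
            counts[f"dmr_{comp}"] = len(dmr_tables[comp])
    else:
        log.append("warning: no sites pass the 1X complete-case filter; DMR branch empty")

    # ---- UMR branch: per-sample 10X ----
    stage("umr")
    rng = np.random.default_rng(config.seed)
    umr_by_sample: dict[str, pd.DataFrame] = {}
    for sample in matrix.samples:
        st = sample_site_table(matrix, sample, min_coverage=config.umr_min_coverage)
        pmds = detect_pmds(st, config)
        umr_by_sample[sample] = segment_umrs(st, config, pmds=pmds, rng=rng)
    case_sets = {s: umr_by_sample[s] for s in matrix.samples if matrix.group[s] != "control"}
    ctrl_sets = {s: umr_by_sample[s] for s in matrix.samples if matrix.group[s] == "control"}
    exclusive = exclusive_umrs(case_sets, ctrl_sets, fraction=config.exclusivity_fraction)
    counts["exclusive_umrs"] = len(exclusive)

    # ---- annotation ----
    annotations = None
    enrichment: dict[str, pd.DataFrame] = {}
    primary = comparisons[0]
    if genes is not None and primary in dmc_tables and len(dmc_tables[primary]):
        stage("annotate")
        annotations = classify_functional(dmc_tables[primary], genes, promoter_bp=config.promoter_bp)
        if islands is not None:
            annotations["cpg_context"] = classify_cpg_context(annotations, islands)
        if categories is not None:
            stage("enrich")
            enrichment = _run_enrichment(annotations, categories)
    gene_set_summary = None
    if gene_sets and annotations is not None and ratios is not None:
        stage("gene-sets")
        sig = annotations[annotations["significant"]]
        dmc_genes = {g for ids in sig["gene_ids"] for g in ids.split(",") if g}
        gene_set_summary = {"intersection": intersect_gene_sets(dmc_genes, gene_sets), "tests": {}}
        for gs in gene_sets:
            try:
                _, tests = geneset_mean_methylation(ratios, gs, genes, promoter_bp=config.promoter_bp)
                gene_set_summary["tests"][gs.name] = tests
            except ValueError as exc:
                log.append(f"gene set {gs.name}: {exc}")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "comparisons": list(comparisons),
        "counts": counts,
        "inputs": {p.name: _checksum(p) for p in (input_paths or [])},
    }
    result = PipelineResult(
        matrix=matrix,
        dmc_tables=dmc_tables,
        dmr_tables=dmr_tables,
        umr_by_sample=umr_by_sample,
        exclusive_umr=exclusive,
        annotations=annotations,
        enrichment=enrichment,
        manifest=manifest,
        log=log,
        gene_set_summary=gene_set_summary,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir), genes, config)
    return result


def _gene_cpg_counts(annotations: pd.DataFrame) -> pd.Series:
    counts: dict[str, int] = {}
    for ids in annotations["gene_ids"]:
        for g in ids.split(","):
            if g:
                counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def _run_enrichment(annotations: pd.DataFrame, categories: dict[str, set[str]]) -> dict[str, pd.DataFrame]:
    """Enrichment for all DMC genes and separately by direction."""
    gene_cpgs = _gene_cpg_counts(annotations)
    out = {}
    for label in ("all", "hypo", "hyper"):
        sig = annotations[annotations["significant"]]
        if label != "all":
            sig = sig[sig["direction"] == label]
        rows = []
        for _, r in sig.iterrows():
            for g in r["gene_ids"].split(","):
                if g:
                    rows.append({"gene_id": g, "delta": r["delta"]})
        dmc_genes_table = pd.DataFrame(rows, columns=["gene_id", "delta"])
        bias = compute_bias(gene_cpgs, dmc_genes_table)
        de = set(dmc_genes_table["gene_id"])
        if not de or len(de) == len(gene_cpgs):
            continue
        try:
            out[label] = enrichment_table(categories, de, bias)
        except ValueError:
            continue
    return out


def _write_outputs(result: PipelineResult, outdir: Path, genes, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for comp, table in result.dmc_tables.items():
        table.to_csv(outdir / f"dmc_{comp}.tsv", sep="\t", index=False)
        sig = table[table["significant"]]
        write_bed(sig, outdir / f"dmc_{comp}.bed", score_field="delta")
        chromosome_summary(table).to_csv(outdir / f"dmc_{comp}_by_chrom.tsv", sep="\t", index=False)
    for comp, regions in result.dmr_tables.items():
        regions.drop(columns=["member_rows"]).to_csv(outdir / f"dmr_{comp}.tsv", sep="\t", index=False)
        write_bed(regions, outdir / f"dmr_{comp}.bed", score_field="mean_delta")
        if genes is not None and len(regions):
            annotate_region_promoters(regions, genes, config.promoter_bp).to_csv(
                outdir / f"dmr_{comp}_promoters.tsv", sep="\t", index=False
            )
    for sample, regions in result.umr_by_sample.items():
        write_bed(regions, outdir / f"umr_{sample}.bed")
    write_bed(result.exclusive_umr, outdir / "umr_exclusive.bed")
    if result.annotations is not None:
        result.annotations.to_csv(outdir / "dmc_annotated.tsv", sep="\t", index=False)
    for label, table in result.enrichment.items():
        table.to_csv(outdir / f"enrichment_{label}.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
    (outdir / "run.log").write_text("\n".join(result.log) + "\n")
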