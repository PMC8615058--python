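"""Site filtering, methylation ratios and batch-effect removal.

The analysis keeps complete-case CpG sites only: a site must reach the
coverage floor in *every* sample and must not exceed the near-saturation
methylation ceiling (pooled methylation > 99.9% suggests bisulfite
non-conversion). Ratios are methylated / total counts. Batch effects — here,
the recruiting origin of the samples — are removed per site by ordinary
least squares on logit-transformed ratios with the group term retained, so
group differences survive the correction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import MethylomeMatrix

__all__ = ["PipelineConfig", "RatioMatrix", "filter_sites", "compute_ratios", "correct_batch"]


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline; defaults are the study criteria.

    min_coverage:      per-sample coverage floor for the DMC/UMR branches (10X)
    max_methylation:   saturation ceiling on the methylation ratio (0.999)
    saturation_scope:  apply the ceiling to the pooled site mean ("site_mean",
                       default) or to every single sample ("any_sample")
    min_delta:         minimum absolute group difference for a DMC (0.08)
    alpha:             FDR level for DMC/DMR significance (0.05)
    neighbor_distance: window (bp) for neighbour p-value combination (200)
    min_dmr_dmcs:      minimum DMCs inside a DMR (2)
    umr_max_meth:      maximum average methylation of a UMR (0.10)
    umr_site_max_meth: per-CpG ceiling inside a UMR candidate run (0.30)
    umr_min_cpgs:      minimum CpGs per UMR candidate (4)
    umr_fdr:           empirical FDR level for UMR regions (0.05)
    umr_permutations:  permutations for the UMR null (20)
    exclusivity_fraction: fraction of case samples a consensus UMR must
                       strictly exceed (0.75)
    promoter_bp:       promoter window upstream of the TSS (1000 bp)
    umr_min_coverage:  per-sample coverage floor for UMR segmentation (10X)
    dmr_min_coverage:  coverage floor for the DMR branch (1X)
    pmd_window_cpgs:   rolling window for PMD detection (101 CpGs)
    pmd_min_cpgs:      minimum run length of a PMD (100 CpGs)
    pmd_band:          rolling-median methylation band defining the PMD state
    batch_correct:     whether group tests use batch-corrected ratios
    welch:             use Welch instead of pooled-variance t
    filter_then_fdr:   apply the 8% floor before (True) or after (False) BH
    """

    min_coverage: int = 10
    max_methylation: float = 0.999
    saturation_scope: str = "site_mean"
    min_delta: float = 0.08
    alpha: float = 0.05
    neighbor_distance: int = 200
    min_dmr_dmcs: int = 2
    umr_max_meth: float = 0.10
    umr_site_max_meth: float = 0.30
    umr_min_cpgs: int = 4
    umr_fdr: float = 0.05
    umr_permutations: int = 20
    exclusivity_fraction: float = 0.75
    promoter_bp: int = 1000
    umr_min_coverage: int = 10
    dmr_min_coverage: int = 1
    pmd_window_cpgs: int = 101
    pmd_min_cpgs: int = 100
    pmd_band: tuple[float, float] = (0.10, 0.60)
    batch_correct: bool = True
    welch: bool = False
    filter_then_fdr: bool = False
    logit_clip: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.max_methylation <= 1):
            raise ValueError("max_methylation must be in (0, 1]")
        if not (0 <= self.min_delta <= 1):
            raise ValueError("min_delta must be in [0, 1]")
        if not (0 < self.alpha < 1) or not (0 < self.umr_fdr < 1):
            raise ValueError("alpha and umr_fdr must be in (0, 1)")
        if not (0 < self.exclusivity_fraction <= 1):
            raise ValueError("exclusivity_fraction must be in (0, 1]")
        if min(self.min_coverage, self.dmr_min_coverage, self.umr_min_coverage) < 1:
            raise ValueError("coverage floors must be >= 1")
        if self.saturation_scope not in ("site_mean", "any_sample"):
            raise ValueError("saturation_scope must be 'site_mean' or 'any_sample'")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["pmd_band"] = list(d["pmd_band"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "pmd_band" in d:
            d["pmd_band"] = tuple(d["pmd_band"])
        return cls(**d)


@dataclass
class RatioMatrix:
    """Methylation ratios (sites x samples) with sample metadata.

    ``corrected`` records whether batch residualization has been applied.
    """

    sites: pd.DataFrame
    ratio: np.ndarray
    samples: list[str]
    group: pd.Series
    batch: pd.Series
    corrected: bool = False

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def group_columns(self, label_or_labels) -> np.ndarray:
        labels = {label_or_labels} if isinstance(label_or_labels, str) else set(label_or_labels)
        mask = np.array([self.group[s] in labels for s in self.samples])
        return self.ratio[:, mask]

    def subset_sites(self, keep: np.ndarray) -> "RatioMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return RatioMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            ratio=self.ratio[idx],
            samples=list(self.samples),
            group=self.group,
            batch=self.batch,
            corrected=self.corrected,
        )


def filter_sites(
    matrix: MethylomeMatrix,
    config: PipelineConfig | None = None,
    min_coverage: int | None = None,
    max_methylation: float | None = None,
    saturation_scope: str | None = None,
    log: list[str] | None = None,
) -> MethylomeMatrix:
    """Keep complete-case sites passing coverage and saturation filters.

    A site is retained iff ``total >= min_coverage`` in every sample and its
    methylation does not exceed ``max_methylation``. Sites missing from any
    sample have ``total = 0`` there and therefore fail the coverage
    condition. Order is preserved; an empty result is a warning downstream,
    not an error.

    The saturation condition has two scopes. ``site_mean`` (default) compares
    the pooled site-level methylation (sum of meth over sum of total across
    samples) with the ceiling: at typical ~15X coverage a per-sample ratio of
    exactly 1.0 is a routine binomial sampling outcome at any truly
    high-methylation site, so the pooled estimate is the meaningful one.
    ``any_sample`` removes a site when any single sample exceeds the ceiling,
    the strictest per-sample reading.
    """
    config = config or PipelineConfig()
    min_cov = config.min_coverage if min_coverage is None else min_coverage
    max_meth = config.max_methylation if max_methylation is None else max_methylation
    scope = config.saturation_scope if saturation_scope is None else saturation_scope

    covered = (matrix.total >= min_cov).all(axis=1)
    if scope == "any_sample":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(matrix.total > 0, matrix.meth / np.maximum(matrix.total, 1), 0.0)
        unsaturated = (ratio <= max_meth).all(axis=1)
    elif scope == "site_mean":
        tot = matrix.total.sum(axis=1)
        pooled = matrix.meth.sum(axis=1) / np.maximum(tot, 1)
        unsaturated = np.where(tot > 0, pooled, 0.0) <= max_meth
    else:
        raise ValueError(f"unknown saturation_scope {scope!r}")
    keep = covered & unsaturated
    if log is not None:
        log.append(f"filter_sites: {matrix.n_sites} -> {int(keep.sum())} "
                   f"(coverage>={min_cov} in all samples: {int(covered.sum())}; "
                   f"methylation<={max_meth} [{scope}]: {int(unsaturated.sum())})")
    return matrix.subset_sites(keep)


def compute_ratios(matrix: MethylomeMatrix) -> RatioMatrix:
    """Per-cell methylation ratio meth/total; filtering must have run first."""
    if (matrix.total == 0).any():
        i, j = np.argwhere(matrix.total == 0)[0]
        site = matrix.sites.iloc[i]
        raise ValueError(
            f"total=0 at {site['chrom']}:{site['pos']} sample {matrix.samples[j]}; run filter_sites first"
        )
    return RatioMatrix(
        sites=matrix.sites.copy(),
        ratio=matrix.meth / matrix.total,
        samples=list(matrix.samples),
        group=matrix.group,
        batch=matrix.batch,
    )


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def correct_batch(ratios: RatioMatrix, clip: float = 0.005) -> RatioMatrix:
    """Remove batch effects per site while keeping group effects.

    Fits, jointly for all sites, OLS of the logit-transformed ratio (clipped
    to [clip, 1-clip]) on an intercept, group indicators and batch indicators;
    subtracts the fitted batch component re-centred to zero mean across
    samples, so the per-site cross-sample mean is preserved exactly in logit
    space; transforms back to the ratio scale.

    Single-batch input is returned unchanged. A batch perfectly confounded
    with group (the joint design is rank-deficient) raises with the offending
    pair named.
    """
    batches = pd.unique(ratios.batch.loc[ratios.samples])
    if len(batches) < 2:
        return RatioMatrix(
            sites=ratios.sites, ratio=ratios.ratio.copy(), samples=list(ratios.samples),
            group=ratios.group, batch=ratios.batch, corrected=True,
        )
    groups = pd.unique(ratios.group.loc[ratios.samples])
    g = ratios.group.loc[ratios.samples].to_numpy()
    b = ratios.batch.loc[ratios.samples].to_numpy()
    n = len(ratios.samples)

    group_cols = [(g == lab).astype(float) for lab in groups[1:]]
    batch_cols = [(b == lab).astype(float) for lab in batches[1:]]
    X = np.column_stack([np.ones(n)] + group_cols + batch_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        pair = _find_confounded_pair(g, b)
        raise ValueError(
            f"batch is confounded with group (e.g. batch {pair[1]!r} coincides with group {pair[0]!r}); "
            "batch effects cannot be separated from group effects"
        )

    Y = _logit(np.clip(ratios.ratio, clip, 1.0 - clip)).T  # samples x sites
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    n_group = len(group_cols)
    batch_part = X[:, 1 + n_group:] @ beta[1 + n_group:, :]
    batch_part -= batch_part.mean(axis=0, keepdims=True)
    corrected = _expit((Y - batch_part).T)
    return RatioMatrix(
        sites=ratios.sites, ratio=corrected, samples=list(ratios.samples),
        group=ratios.group, batch=ratios.batch, corrected=True,
    )


def _find_confounded_pair(g: np.ndarray, b: np.ndarray) -> tuple[str, str]:
    for batch in pd.unique(b):
        in_batch = b == batch
        gl = set(g[in_batch])
        if len(gl) == 1:
            lab = next(iter(gl))
            if set(b[g == lab]) == {batch}:
                return (lab, batch)
    return (str(pd.unique(g)[0]), str(pd.unique(b)[0]))
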