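"""Readers and writers for the file formats a WGBS methylome pipeline touches.

All internal coordinates are 0-based half-open. A CpG site is keyed by the
position of the cytosine on the plus strand; per-strand cytosine records at
``pos`` and ``pos + 1`` describe the same CpG and are collapsed by summing
their counts, since downstream statistics are per CpG site, not per strand.

Supported inputs
----------------
* Bismark coverage files (``.cov``/``.cov.gz``): 1-based inclusive
  ``chrom  start  end  %meth  count_meth  count_unmeth``.
* Generic count TSVs: 0-based half-open
  ``chrom  start  end  count_meth  count_total``.
* Sample sheets: TSV with columns ``sample``, ``group`` and optionally
  ``batch`` (a single batch ``batch0`` is assumed when absent).
* BED3/BED6 interval tracks (CpG islands, masks), BED12-lite gene tables.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_GROUPS = ("control", "MDH", "MDL")

__all__ = [
    "CpGSite",
    "MethylomeMatrix",
    "GeneModel",
    "IntervalTrack",
    "read_coverage_file",
    "read_sample_sheet",
    "assemble_matrix",
    "write_coverage_file",
    "write_bed",
    "read_bed",
    "read_gene_table",
]


@dataclass(frozen=True)
class CpGSite:
    """A CpG site keyed by the plus-strand C position (0-based)."""

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos} on {self.chrom}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class GeneModel:
    """Minimal transcript model: span, strand and exon/UTR structure.

    ``tx_start``/``tx_end`` are 0-based half-open; exon and UTR intervals are
    lists of (start, end) tuples inside the span, non-overlapping per class.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start >= tx_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: gene without strand")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start (a 0-based base position)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def promoter(self, promoter_bp: int = 1000) -> tuple[int, int]:
        """Promoter window upstream of the TSS, 0-based half-open.

        Plus strand: ``[TSS - promoter_bp, TSS)``; minus strand:
        ``[tx_end, tx_end + promoter_bp)``.
        """
        if self.strand == "+":
            return (max(0, self.tx_start - promoter_bp), self.tx_start)
        return (self.tx_end, self.tx_end + promoter_bp)


@dataclass
class IntervalTrack:
    """A named set of genomic intervals, 0-based half-open, sorted and merged."""

    name: str
    intervals: pd.DataFrame  # columns: chrom, start, end

    @classmethod
    def from_tuples(cls, name: str, tuples: Iterable[tuple[str, int, int]]) -> "IntervalTrack":
        df = pd.DataFrame(list(tuples), columns=["chrom", "start", "end"])
        return cls(name=name, intervals=merge_intervals(df))


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort intervals and merge overlapping/adjacent ones per chromosome."""
    if len(df) == 0:
        return df.copy()
    bad = df["start"] >= df["end"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(f"empty interval {row['chrom']}:{row['start']}-{row['end']}")
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    out: list[list] = []
    for chrom, start, end in df[["chrom", "start", "end"]].itertuples(index=False):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1][2] = max(out[-1][2], end)
        else:
            out.append([chrom, start, end])
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


@dataclass
class MethylomeMatrix:
    """CpG sites x samples matrix of methylated / total read counts.

    ``sites`` has columns ``chrom`` and ``pos`` (plus-strand C position),
    sorted by (chrom, pos) and unique. ``meth`` and ``total`` are integer
    arrays of shape (n_sites, n_samples); a (site, sample) pair the sample
    never covered is stored with ``total == 0``, never as NaN. ``group`` and
    ``batch`` are per-sample labels aligned with ``samples``.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: list[str]
    group: pd.Series
    batch: pd.Series

    def __post_init__(self) -> None:
        n_sites, n_samples = self.meth.shape
        if self.total.shape != (n_sites, n_samples):
            raise ValueError("meth and total shapes differ")
        if len(self.sites) != n_sites or len(self.samples) != n_samples:
            raise ValueError("site/sample labels do not match matrix shape")
        if (self.meth > self.total).any():
            raise ValueError("meth_count exceeds total_count")
        if (self.meth < 0).any() or (self.total < 0).any():
            raise ValueError("negative counts")
        for s in self.samples:
            if s not in self.group.index or s not in self.batch.index:
                raise ValueError(f"sample {s} missing group or batch label")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[n] for n in names], dtype=int)

    def subset_sites(self, keep: np.ndarray) -> "MethylomeMatrix":
        """Row-subset by boolean mask or integer index, order preserved."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return MethylomeMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            meth=self.meth[idx],
            total=self.total[idx],
            samples=list(self.samples),
            group=self.group,
            batch=self.batch,
        )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_coverage_file(path: str | Path, dialect: str = "bismark_cov", collapse_strands: bool = True) -> pd.DataFrame:
    """Read one sample's CpG counts into a table of 0-based plus-strand sites.

    Parameters
    ----------
    path:
        Coverage file; ``.gz`` transparently decompressed.
    dialect:
        ``bismark_cov`` — 1-based inclusive columns
        (chrom, start, end, %meth, n_meth, n_unmeth); the percentage column is
        ignored in favour of the counts. ``generic_tsv`` — 0-based half-open
        (chrom, start, end, n_meth, n_total).
    collapse_strands:
        Sum a minus-strand record at ``pos + 1`` into the plus-strand CpG at
        ``pos`` when both are present.

    Returns
    -------
    DataFrame with columns ``chrom``, ``pos``, ``meth``, ``total`` sorted by
    (chrom, pos).
    """
    if dialect not in ("bismark_cov", "generic_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            try:
                if dialect == "bismark_cov":
                    if len(parts) < 6:
                        raise ValueError("expected 6 columns")
                    chrom, start = parts[0], int(parts[1])
                    meth, unmeth = int(parts[4]), int(parts[5])
                    if meth < 0 or unmeth < 0:
                        raise ValueError("negative count")
                    pos, total = start - 1, meth + unmeth
                else:
                    if len(parts) < 5:
                        raise ValueError("expected 5 columns")
                    chrom, pos = parts[0], int(parts[1])
                    meth, total = int(parts[3]), int(parts[4])
                if pos < 0:
                    raise ValueError("negative position")
                if meth < 0 or total < 0 or meth > total:
                    raise ValueError(f"bad counts meth={meth} total={total}")
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from None
            rows.append((chrom, pos, meth, total))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    df = df.groupby(["chrom", "pos"], as_index=False, sort=True).sum()
    if collapse_strands and len(df):
        df = _collapse_cpg_strands(df)
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _collapse_cpg_strands(df: pd.DataFrame) -> pd.DataFrame:
    """Fold records at pos+1 into an existing record at pos (per chromosome)."""
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    is_minus = np.zeros(len(df), dtype=bool)
    is_minus[1:] = (chrom[1:] == chrom[:-1]) & (pos[1:] == pos[:-1] + 1)
    # a record only folds into a genuine plus-strand anchor, not another folded one
    is_minus[1:] &= ~is_minus[:-1]
    if not is_minus.any():
        return df
    anchor = np.arange(len(df))
    anchor[is_minus] -= 1
    out = df.copy()
    out["pos"] = pos[anchor]
    return out.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "total"]].sum()


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet TSV (columns sample, group[, batch])."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in sheet.columns or "group" not in sheet.columns:
        raise ValueError("sample sheet needs 'sample' and 'group' columns")
    if "batch" not in sheet.columns:
        sheet["batch"] = "batch0"
    sheet["batch"] = sheet["batch"].fillna("batch0")
    return sheet[["sample", "group", "batch"]]


def assemble_matrix(tables: dict[str, pd.DataFrame], sheet: pd.DataFrame) -> MethylomeMatrix:
    """Join per-sample count tables on the union of sites.

    Sites absent from a sample get ``total = 0`` for that column. Every sample
    in ``tables`` must appear exactly once in the sheet, groups must be one of
    ``control``/``MDH``/``MDL``.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 samples")
    sheet = sheet.copy()
    if "batch" not in sheet.columns:
        sheet["batch"] = "batch0"
    if sheet["sample"].duplicated().any():
        dup = sheet.loc[sheet["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in sample sheet")
    unknown = set(sheet["group"]) - set(VALID_GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s) {sorted(unknown)}; expected {VALID_GROUPS}")
    missing = set(tables) - set(sheet["sample"])
    if missing:
        raise ValueError(f"samples missing from sheet: {sorted(missing)}")
    samples = [s for s in sheet["sample"] if s in tables]

    key_frames = [t[["chrom", "pos"]] for t in tables.values()]
    sites = (
        pd.concat(key_frames, ignore_index=True)
        .drop_duplicates()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    index = pd.MultiIndex.from_frame(sites)
    n = len(sites)
    meth = np.zeros((n, len(samples)), dtype=np.int64)
    total = np.zeros((n, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        t = tables[s].set_index(["chrom", "pos"])
        aligned = t.reindex(index)
        m = aligned["meth"].to_numpy()
        tt = aligned["total"].to_numpy()
        found = ~np.isnan(tt)
        meth[found, j] = m[found].astype(np.int64)
        total[found, j] = tt[found].astype(np.int64)
    sheet_idx = sheet.set_index("sample")
    return MethylomeMatrix(
        sites=sites,
        meth=meth,
        total=total,
        samples=samples,
        group=sheet_idx["group"].loc[samples],
        batch=sheet_idx["batch"].loc[samples],
    )


def write_coverage_file(df: pd.DataFrame, path: str | Path, dialect: str = "bismark_cov") -> None:
    """Write a per-sample count table in the chosen dialect (inverse of read)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt") as fh:
        for chrom, pos, meth, total in df[["chrom", "pos", "meth", "total"]].itertuples(index=False):
            if dialect == "bismark_cov":
                pct = 100.0 * meth / total if total else 0.0
                fh.write(f"{chrom}\t{pos + 1}\t{pos + 1}\t{pct:.6g}\t{meth}\t{total - meth}\n")
            elif dialect == "generic_tsv":
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{meth}\t{total}\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def write_bed(records: pd.DataFrame, path: str | Path, score_field: str | None = None) -> None:
    """Write intervals (or single sites) as BED, 0-based half-open.

    ``records`` needs ``chrom`` plus either ``start``/``end`` or ``pos`` (a
    site becomes a 1-bp interval). With ``score_field`` set, emits BED5-style
    lines ``chrom start end . score`` with the score at 6 decimals.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = records.copy()
    if "start" not in df.columns:
        df["start"] = df["pos"]
        df["end"] = df["pos"] + 1
    try:
        df = df.sort_values(["chrom", "start"], kind="mergesort")
    except TypeError as exc:
        raise ValueError(f"unsortable chromosome values: {exc}") from None
    with open(path, "wt") as fh:
        if len(df) == 0:
            fh.write("# no records\n")
            return
        for _, row in df.iterrows():
            line = f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}"
            if score_field is not None:
                line += f"\t.\t{float(row[score_field]):.6f}"
            fh.write(line + "\n")


def read_bed(path: str | Path, name: str = "track") -> IntervalTrack:
    """Read a BED3+ file into a merged IntervalTrack."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return IntervalTrack.from_tuples(name, rows)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a minimal gene table TSV.

    Columns: gene_id, chrom, strand, tx_start, tx_end, exons, utr5, utr3 where
    interval-list columns are ``start-end`` pairs joined by commas (empty
    string for none).
    """

    def parse_ivs(cell: str) -> list[tuple[int, int]]:
        if not isinstance(cell, str) or not cell:
            return []
        out = []
        for part in cell.split(","):
            a, b = part.split("-")
            out.append((int(a), int(b)))
        return out

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str}, keep_default_na=False)
    genes = []
    for _, r in df.iterrows():
        genes.append(
            GeneModel(
                gene_id=r["gene_id"],
                chrom=r["chrom"],
                strand=r["strand"],
                tx_start=int(r["tx_start"]),
                tx_end=int(r["tx_end"]),
                exons=parse_ivs(r.get("exons", "")),
                utr5=parse_ivs(r.get("utr5", "")),
                utr3=parse_ivs(r.get("utr3", "")),
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    def fmt(ivs: list[tuple[int, int]]) -> str:
        return ",".join(f"{a}-{b}" for a, b in ivs)

    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tx_start": g.tx_start,
            "tx_end": g.tx_end,
            "exons": fmt(g.exons),
            "utr5": fmt(g.utr5),
            "utr3": fmt(g.utr3),
        }
        for g in genes
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
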