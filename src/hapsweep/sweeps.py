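"""Sweep-region calling, per-chromosome summaries, QTL overlap and enrichment.

Significant SNPs (q below threshold) are merged into sweep regions, the
regions are summarized per chromosome (count, size, SNPs and genes per
sweep, genome coverage), intersected with externally mapped QTL intervals,
and the sweep coverage of QTL vs the whole genome is compared with a
chi-square test on base-pair counts.  All coordinates are 1-based
inclusive internally; BED I/O converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SweepRegion",
    "QTLInterval",
    "OverlapReport",
    "call_sweeps",
    "annotate_genes",
    "summarize_by_chromosome",
    "overall_summary",
    "overlap_qtl",
    "coverage_enrichment",
    "expected_sweep_size",
    "read_qtl_bed",
    "write_sweeps_bed",
]


@dataclass
class SweepRegion:
    """A genomic interval delimited by its outermost significant SNPs."""

    chrom: str
    start: int
    end: int
    n_snps_total: int
    n_snps_significant: int
    genes: list = field(default_factory=list)

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end


@dataclass
class QTLInterval:
    id: str
    chrom: str
    start: int
    end: int
    significance: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"QTL {self.id}: start must be < end")

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class OverlapReport:
    per_qtl: dict            # qtl id -> list of SweepRegion
    cov_genome: float        # fraction of the genome covered by sweeps
    cov_qtl: float           # fraction of QTL bp covered by sweeps
    chi2: float
    p: float
    cov_qtl_colocalized: float  # denominator restricted to QTL with >=1 sweep


def call_sweeps(scan_table, q_threshold: float = 0.1,
                merge_gap: int = 50_000) -> list:
    """Group significant SNPs into sweep regions.

    ``scan_table`` is a DataFrame with columns chrom, pos, q (a
    ScanResult works via its ``.table``).  Consecutive significant SNPs on
    a chromosome are merged while their gap is <= merge_gap bp; regions
    with fewer than two significant SNPs are discarded.  Boundaries are
    the outermost significant SNP positions; n_snps_total counts every
    analyzed SNP inside them.
    """
    df = getattr(scan_table, "table", scan_table)
    regions: list[SweepRegion] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        sig = pos[(sub["q"] < q_threshold).to_numpy()]
        if len(sig) == 0:
            continue
        breaks = np.flatnonzero(np.diff(sig) > merge_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(sig) - 1]])
        for a, b in zip(starts, ends):
            n_sig = b - a + 1
            if n_sig < 2:
                continue
            lo, hi = int(sig[a]), int(sig[b])
            n_tot = int(((pos >= lo) & (pos <= hi)).sum())
            regions.append(SweepRegion(chrom=str(chrom), start=lo, end=hi,
                                       n_snps_total=n_tot,
                                       n_snps_significant=n_sig))
    return regions


def annotate_genes(regions: Sequence[SweepRegion], gff: str | Path) -> list:
    """Attach overlapping gene IDs to each region (partial overlap counts).

    ``gff`` is a GFF3 path; features of type ``gene`` are used.
    """
    import gffutils

    try:
        db = gffutils.create_db(str(gff), dbfn=":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
    except Exception as e:  # noqa: BLE001 - surface parse location
        raise ValueError(f"malformed GFF3 {gff}: {e}") from e
    genes = [(f.seqid, f.start, f.end, f.id) for f in db.features_of_type("gene")]
    out = []
    for r in regions:
        hits = [gid for (c, s, e, gid) in genes
                if r.overlaps(c, s, e)]
        out.append(SweepRegion(chrom=r.chrom, start=r.start, end=r.end,
                               n_snps_total=r.n_snps_total,
                               n_snps_significant=r.n_snps_significant,
                               genes=sorted(hits)))
    return out


def summarize_by_chromosome(regions: Sequence[SweepRegion],
                            chrom_sizes: Mapping[str, int]) -> pd.DataFrame:
    """Per-chromosome sweep summary (one row per chromosome with sweeps).

    Columns: chrom, chrom_size_mb, n_sweeps, size mean/min/max (kb),
    coverage_pct, SNPs per sweep mean/min/max, genes per sweep
    mean/min/max/total.
    """
    rows = []
    by_chrom: dict[str, list[SweepRegion]] = {}
    for r in regions:
        if r.chrom not in chrom_sizes:
            raise ValueError(f"chromosome {r.chrom} missing from chrom_sizes")
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in chrom_sizes:
        rs = by_chrom.get(chrom)
        if not rs:
            continue
        sizes = np.array([r.size_bp for r in rs], dtype=float)
        snps = np.array([r.n_snps_total for r in rs], dtype=float)
        ngenes = np.array([len(r.genes) for r in rs], dtype=float)
        rows.append({
            "chrom": chrom,
            "chrom_size_mb": chrom_sizes[chrom] / 1e6,
            "n_sweeps": len(rs),
            "mean_kb": sizes.mean() / 1e3,
            "min_kb": sizes.min() / 1e3,
            "max_kb": sizes.max() / 1e3,
            "coverage_pct": 100.0 * sizes.sum() / chrom_sizes[chrom],
            "snps_mean": snps.mean(),
            "snps_min": snps.min(),
            "snps_max": snps.max(),
            "genes_mean": ngenes.mean(),
            "genes_min": ngenes.min(),
            "genes_max": ngenes.max(),
            "genes_total": int(ngenes.sum()),
        })
    return pd.DataFrame(rows)


def overall_summary(per_chrom: pd.DataFrame, genome_size_mb: float) -> dict:
    """Genome-wide roll-up of a per-chromosome summary table.

    Total coverage is the size-weighted combination
    sum_c(coverage_c * size_c) / genome size.  The headline mean sweep
    size and mean SNPs/sweep are *unweighted* means of the per-chromosome
    means (the convention of the published chicken table); sweep-weighted
    variants are also returned, labelled.
    """
    cov = (per_chrom["coverage_pct"] * per_chrom["chrom_size_mb"]).sum() \
        / genome_size_mb
    n = per_chrom["n_sweeps"].to_numpy(dtype=float)
    out = {
        "n_sweeps": int(n.sum()),
        "coverage_pct": float(cov),
        "mean_size_kb": float(per_chrom["mean_kb"].mean()),
        "mean_snps_per_sweep": float(per_chrom["snps_mean"].mean()),
        "mean_genes_per_sweep": float(per_chrom["genes_mean"].mean()),
        "mean_size_kb_weighted": float((per_chrom["mean_kb"] * n).sum() / n.sum()),
        "mean_snps_per_sweep_weighted": float(
            (per_chrom["snps_mean"] * n).sum() / n.sum()),
    }
    return out


def _merged_intervals(intervals):
    """Merge 1-based inclusive (chrom, start, end) tuples."""
    merged: dict[str, list[list[int]]] = {}
    for c, s, e in sorted(intervals):
        lst = merged.setdefault(c, [])
        if lst and s <= lst[-1][1] + 1:
            lst[-1][1] = max(lst[-1][1], e)
        else:
            lst.append([s, e])
    return merged


def _total_bp(merged) -> int:
    return sum(e - s + 1 for lst in merged.values() for s, e in lst)


def _intersection_bp(merged_a, merged_b) -> int:
    total = 0
    for c, la in merged_a.items():
        lb = merged_b.get(c, [])
        j = 0
        for s, e in la:
            for s2, e2 in lb:
                lo, hi = max(s, s2), min(e, e2)
                if lo <= hi:
                    total += hi - lo + 1
    return total


def overlap_qtl(regions: Sequence[SweepRegion],
                qtls: Sequence[QTLInterval]) -> dict:
    """Sweeps colocalizing with each QTL (interval intersection)."""
    return {q.id: [r for r in regions if r.overlaps(q.chrom, q.start, q.end)]
            for q in qtls}


def coverage_enrichment(regions: Sequence[SweepRegion],
                        qtls: Sequence[QTLInterval],
                        genome_size: int) -> OverlapReport:
    """Sweep coverage of QTL vs the genome, with a 1-df chi-square test.

    Builds the 2x2 base-pair table {sweep, non-sweep} x {QTL, non-QTL}
    and applies Pearson's chi-square without continuity correction.
    """
    if not qtls:
        raise ValueError("empty QTL set: enrichment undefined")
    sweep_m = _merged_intervals([(r.chrom, r.start, r.end) for r in regions])
    qtl_m = _merged_intervals([(q.chrom, q.start, q.end) for q in qtls])
    sweep_bp = _total_bp(sweep_m)
    qtl_bp = _total_bp(qtl_m)
    inter = _intersection_bp(sweep_m, qtl_m)
    table = np.array([
        [inter, sweep_bp - inter],
        [qtl_bp - inter, genome_size - qtl_bp - (sweep_bp - inter)],
    ], dtype=float)
    if sweep_bp > 0:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        chi2, p = 0.0, 1.0

    per_qtl = overlap_qtl(regions, qtls)
    coloc = [q for q in qtls if per_qtl[q.id]]
    coloc_m = _merged_intervals([(q.chrom, q.start, q.end) for q in coloc])
    coloc_bp = _total_bp(coloc_m)
    cov_coloc = (_intersection_bp(sweep_m, coloc_m) / coloc_bp
                 if coloc_bp else float("nan"))
    return OverlapReport(
        per_qtl=per_qtl,
        cov_genome=sweep_bp / genome_size,
        cov_qtl=inter / qtl_bp,
        chi2=float(chi2),
        p=float(p),
        cov_qtl_colocalized=cov_coloc,
    )


def expected_sweep_size(n: float, rho: float, T: float) -> float:
    """Approximate expected sweep size 1 / (n * rho * T) in bp.

    n is the haploid sample size, rho the per-bp per-generation
    recombination rate and T the total number of generations over which
    recombination has broken up the swept haplotype.
    """
    if n <= 0 or rho <= 0 or T <= 0:
        raise ValueError("all parameters must be positive")
    return 1.0 / (n * rho * T)


def read_qtl_bed(path: str | Path) -> list:
    """Read QTL intervals from BED (0-based half-open -> 1-based inclusive)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"qtl{i}"
            out.append(QTLInterval(id=name, chrom=chrom,
                                   start=start + 1, end=end))
    return out


def write_sweeps_bed(regions: Sequence[SweepRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tsweep{i}\t"
                     f"{r.n_snps_significant}\n")
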