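"""Genotype containers, VCF I/O, allele frequencies and SNP filtering.

The central container is :class:`GenotypeMatrix`: biallelic SNP dosages
(count of alternate alleles, 0/1/2, ``-1`` for missing) for a set of
individuals carrying population labels.  In the divergent-line design the
labels distinguish the two selected F0 lines from the F1 crosses; kinship
and frequency computations use F0 individuals only, while haplotype-cluster
inference uses everyone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "FreqTable",
    "FilterConfig",
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "allele_frequencies",
    "filter_maf",
    "subsample_snps",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent user-supplied configuration."""


class InputError(ValueError):
    """Raised for malformed input files."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages with individual population labels.

    Parameters
    ----------
    individuals : sequence of str
        Individual identifiers (length N).
    populations : sequence of str
        Population label per individual, e.g. ``"lineA"``, ``"lineB"``,
        ``"F1"``.
    chrom, pos : arrays of length S
        Chromosome name and 1-based physical position per SNP; positions
        must be strictly increasing within each chromosome.
    ref, alt : arrays of length S
        Reference and alternate alleles.
    dosage : (N, S) int8 array
        Count of alternate alleles, ``-1`` for missing.
    """

    individuals: np.ndarray
    populations: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.individuals), len(self.pos)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.pos)} SNPs"
            )
        if len(self.populations) != len(self.individuals):
            raise ValueError("one population label per individual required")
        bad = (self.dosage < -1) | (self.dosage > 2)
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset SNPs by (sorted) integer index or boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosage=self.dosage[:, index],
        )

    def take_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            individuals=self.individuals[mask],
            populations=self.populations[mask],
            dosage=self.dosage[mask, :],
        )

    def population_mask(self, labels: Sequence[str]) -> np.ndarray:
        labels = set(labels)
        return np.array([p in labels for p in self.populations])


@dataclass
class FreqTable:
    """Per-SNP allele frequencies by population plus MAF and call rate.

    ``freq[pop]`` is the alternate-allele frequency computed over
    non-missing genotypes of that population (NaN where the population has
    no calls at a SNP).  ``maf`` and ``call_rate`` are computed over all
    individuals.
    """

    populations: list
    freq: dict
    maf: np.ndarray
    call_rate: np.ndarray


@dataclass
class FilterConfig:
    """SNP filtering and subsampling parameters.

    maf_min
        SNPs with minor-allele frequency strictly below this are removed
        (boundary MAF == maf_min is retained).
    kinship_fraction, scan_fraction
        Fractions of the retained high-frequency SNPs used for kinship
        estimation and for the haplotype scan.
    """

    maf_min: float = 0.10
    kinship_fraction: float = 0.01
    scan_fraction: float = 0.30
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_min", "kinship_fraction", "scan_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")


def read_population_map(path: str | Path) -> dict:
    """Read a two-column TSV (sample, label) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["label"]))


def read_vcf(path: str | Path, population_map: Mapping[str, str]) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records and indels are excluded (counts are logged).
    Every sample in the VCF must appear in ``population_map``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in population_map]
    if missing_samples:
        raise ConfigurationError(
            f"samples absent from population map: {missing_samples}"
        )

    chrom, pos, ref, alt, cols = [], [], [], [], []
    n_multi = n_indel = 0
    last: dict = {}
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_indel += 1
            continue
        p = rec.POS
        if rec.CHROM in last and p <= last[rec.CHROM]:
            raise InputError(
                f"VCF not position-sorted at {rec.CHROM}:{p}"
            )
        last[rec.CHROM] = p
        chrom.append(rec.CHROM)
        pos.append(p)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        # gts012: 0/1/2 = alt dosage, 3 = missing
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        cols.append(g)
    if n_multi or n_indel:
        logger.info(
            "read_vcf: excluded %d multiallelic and %d indel records",
            n_multi, n_indel,
        )
    dosage = (
        np.stack(cols, axis=1) if cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        individuals=np.array(samples, dtype=object),
        populations=np.array([population_map[s] for s in samples], dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=dosage,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path,
              chrom_sizes: Mapping[str, int] | None = None) -> None:
    """Write a minimal GT-only VCF 4.2 (uncompressed text)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if chrom_sizes:
            for c, L in chrom_sizes.items():
                fh.write(f"##contig=<ID={c},length={L}>\n")
        else:
            for c in pd.unique(g.chrom):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in g.individuals) + "\n")
        for s in range(g.n_snps):
            gts = "\t".join(_GT_STR[int(d)] for d in g.dosage[:, s])
            fh.write(
                f"{g.chrom[s]}\t{g.pos[s]}\t.\t{g.ref[s]}\t{g.alt[s]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def allele_frequencies(g: GenotypeMatrix,
                       f0_populations: Sequence[str] | None = None) -> FreqTable:
    """Alternate-allele frequency per F0 population, plus MAF and call rate.

    Frequencies are alt-dosage sums over twice the non-missing count.
    ``f0_populations`` defaults to every label except ``"F1"``; MAF and
    call rate are always computed over *all* individuals, since the
    low-frequency filter is applied before any population split.
    """
    if f0_populations is None:
        f0_populations = [p for p in pd.unique(g.populations) if p != "F1"]

    d = g.dosage
    obs = d != MISSING
    dd = np.where(obs, d, 0).astype(np.float64)

    freq = {}
    for popl in f0_populations:
        m = g.populations == popl
        n_called = obs[m].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = dd[m].sum(axis=0) / (2.0 * n_called)
        f[n_called == 0] = np.nan
        freq[popl] = f

    n_all = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_all = dd.sum(axis=0) / (2.0 * n_all)
    f_all[n_all == 0] = np.nan
    maf = np.minimum(f_all, 1.0 - f_all)
    call_rate = n_all / g.n_individuals
    return FreqTable(populations=list(f0_populations), freq=freq,
                     maf=maf, call_rate=call_rate)


def filter_maf(g: GenotypeMatrix, f: FreqTable,
               cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Remove SNPs with MAF strictly below ``cfg.maf_min``.

    SNPs with any F0 population entirely missing are also dropped (their
    population frequencies are undefined downstream); the count is logged.
    """
    cfg = cfg or FilterConfig()
    keep = np.asarray(f.maf >= cfg.maf_min) & np.isfinite(f.maf)
    n_popmiss = 0
    for popl in f.populations:
        miss = ~np.isfinite(f.freq[popl])
        n_popmiss += int((keep & miss).sum())
        keep &= ~miss
    if n_popmiss:
        logger.info("filter_maf: dropped %d SNPs with a fully-missing "
                    "population", n_popmiss)
    if not keep.any():
        logger.warning("filter_maf: no SNPs pass MAF >= %.3f", cfg.maf_min)
    return g.take_snps(keep)


def subsample_snps(g: GenotypeMatrix, fraction: float,
                   seed: int) -> GenotypeMatrix:
    """Uniform random subset of round(fraction * S) SNPs, order preserved."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError(f"fraction={fraction} outside (0, 1]")
    if fraction == 1.0:
        return g
    rng = np.random.default_rng(seed)
    n = int(round(fraction * g.n_snps))
    idx = np.sort(rng.choice(g.n_snps, size=n, replace=False))
    return g.take_snps(idx)
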