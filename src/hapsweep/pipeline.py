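"""End-to-end sweep-detection pipeline on a genotype matrix.

filter (MAF) -> kinship (Reynolds on a 1% subsample of F0 genotypes) ->
haplotype-cluster scan (30% subsample, F1 included in cluster inference)
-> null calibration -> sweep calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import ClusterConfig
from .genotypes import (FilterConfig, GenotypeMatrix, allele_frequencies,
                        filter_maf, subsample_snps)
from .kinship import KinshipMatrix, kinship_from_distances, reynolds_matrix
from .scan import ScanConfig, ScanResult, scan
from .sweeps import call_sweeps

__all__ = ["PipelineResult", "estimate_kinship", "run_scan"]


@dataclass
class PipelineResult:
    kinship: KinshipMatrix
    scan: ScanResult
    sweeps: list
    n_snps_input: int
    n_snps_maf: int
    n_snps_scan: int


def estimate_kinship(g: GenotypeMatrix, cfg: FilterConfig,
                     f0_populations: list | None = None) -> KinshipMatrix:
    """Reynolds-distance kinship from a subsample of F0 genotypes."""
    sub = subsample_snps(g, cfg.kinship_fraction, cfg.subsample_seed)
    f0_mask = sub.populations != "F1"
    sub = sub.take_individuals(f0_mask)
    freqs = allele_frequencies(sub, f0_populations)
    D = reynolds_matrix(freqs.freq, freqs.populations)
    return kinship_from_distances(D, labels=freqs.populations)


def run_scan(g: GenotypeMatrix,
             fcfg: FilterConfig | None = None,
             ccfg: ClusterConfig | None = None,
             scfg: ScanConfig | None = None,
             merge_gap: int = 50_000) -> PipelineResult:
    fcfg = fcfg or FilterConfig()
    ccfg = ccfg or ClusterConfig()
    scfg = scfg or ScanConfig()
    freqs = allele_frequencies(g)
    hf = filter_maf(g, freqs, fcfg)
    kin = estimate_kinship(hf, fcfg)
    g_scan = subsample_snps(hf, fcfg.scan_fraction, fcfg.subsample_seed + 1)
    res = scan(g_scan, kin, ccfg, scfg)
    sweeps = call_sweeps(res.table, q_threshold=scfg.q_threshold,
                         merge_gap=merge_gap)
    return PipelineResult(kinship=kin, scan=res, sweeps=sweeps,
                          n_snps_input=g.n_snps, n_snps_maf=hf.n_snps,
                          n_snps_scan=g_scan.n_snps)
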