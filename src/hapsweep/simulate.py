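"""Forward-in-time simulator of a divergent-selection breeding design.

The stated world mirrors a classic poultry experiment: a foundation stock
mixed from six ancestral meat lines (23 sires, 68 dams), seven
generations of divergent truncation selection on an additive trait
producing an up-selected line A and a down-selected line B, then 28
generations of maintenance with 20 sires per line, and finally sequencing
of 4 line-A, 7 line-B and 9 F1 (A x B) birds.  SNPs are placed at ~2.6
per kb, meioses place crossovers as a Poisson process at 3e-8 per bp per
generation, and founder linkage disequilibrium is induced by emitting
founder haplotypes as mosaics of ancestral-line-specific frequency
profiles — exactly the structure the K=6 haplotype-cluster model assumes.

The default simulated genome is 5 chromosomes of 10 Mb, not a full
1 Gb genome; power and calibration properties are stated at that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, write_vcf
from .sweeps import QTLInterval

__all__ = [
    "DesignParams",
    "Genome",
    "Founders",
    "SimulationTruth",
    "Fixtures",
    "make_genome",
    "make_founders",
    "meiosis",
    "simulate_design",
    "make_fixtures",
    "effective_size",
    "write_gff3",
    "write_qtl_bed",
]


@dataclass
class DesignParams:
    """Breeding-design and genome parameters (defaults = the stated world)."""

    n_ancestral_lines: int = 6
    founder_sires: int = 23
    founder_dams: int = 68
    selection_generations: int = 7
    maintenance_generations: int = 28
    sires_per_generation: int = 20
    dams_per_generation: int = 60
    selected_fraction: float = 0.25
    n_qtn: int = 1
    qtn_effects: tuple | None = None
    heritability: float = 0.5
    recomb_rate: float = 3e-8
    snp_density: float = 2.6          # SNPs per kb
    chrom_lengths: tuple = (10_000_000,) * 5
    line_divergence: float = 0.2      # Balding-Nichols F among ancestral lines
    founder_switch_rate: float = 1e-6  # ancestry switches per bp in founders
    prototypes_per_line: int = 3      # distinct haplotypes segregating per line
    prototype_switch_rate: float = 5e-6  # within-line prototype switches per bp
    mutation_noise: float = 0.01      # per-SNP allele flip on founder haplotypes
    n_sample_a: int = 4
    n_sample_b: int = 7
    n_sample_f1: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must lie in (0, 1]")
        for name in ("n_ancestral_lines", "founder_sires", "founder_dams",
                     "selection_generations", "maintenance_generations",
                     "sires_per_generation", "dams_per_generation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.qtn_effects is None:
            self.qtn_effects = (1.0,) * self.n_qtn
        if len(self.qtn_effects) != self.n_qtn:
            raise ValueError("qtn_effects length must equal n_qtn")

    @property
    def candidates_per_line(self) -> int:
        need = self.sires_per_generation + self.dams_per_generation
        n = int(np.ceil(need / self.selected_fraction))
        if n // 2 < self.sires_per_generation or \
                n - n // 2 < self.dams_per_generation:
            raise ValueError(
                "selected_fraction x candidates leaves too few parents")
        return n


@dataclass
class Genome:
    chrom_names: list
    chrom_lengths: list
    snp_chrom_idx: np.ndarray   # (S,) index into chrom_names
    snp_pos: np.ndarray         # (S,) 1-based bp

    @property
    def n_snps(self) -> int:
        return len(self.snp_pos)

    def chrom_slice(self, c: int) -> slice:
        idx = np.flatnonzero(self.snp_chrom_idx == c)
        return slice(idx[0], idx[-1] + 1) if len(idx) else slice(0, 0)


@dataclass
class Founders:
    haplotypes: np.ndarray      # (n_founders, 2, S) uint8
    lines: np.ndarray           # ancestral-line assignment per founder
    is_male: np.ndarray
    line_freqs: np.ndarray      # (n_lines, S)


@dataclass
class SimulationTruth:
    qtn_snp_index: np.ndarray
    qtn_chrom: list
    qtn_pos: np.ndarray
    qtn_effects: np.ndarray
    line_means: pd.DataFrame    # generation, line, mean_gv, mean_phenotype
    qtn_freqs: pd.DataFrame     # line x QTN final alt-allele frequency
    pedigree: pd.DataFrame      # generation, line, n_sires, n_dams
    genome: Genome
    sampled_snp_index: np.ndarray  # genome SNP index of each emitted SNP


@dataclass
class Fixtures:
    genes: pd.DataFrame         # gene_id, chrom, start, end
    qtls: list
    ase: pd.DataFrame
    ct: pd.DataFrame


# --------------------------------------------------------------------------
# genome and founders

def make_genome(params: DesignParams, rng: np.random.Generator) -> Genome:
    """Poisson-placed SNP positions at ``snp_density`` per kb."""
    chrom_names = [f"chr{i + 1}" for i in range(len(params.chrom_lengths))]
    idx, pos = [], []
    for c, L in enumerate(params.chrom_lengths):
        n = rng.poisson(params.snp_density * L / 1000.0)
        p = np.sort(rng.choice(L, size=min(n, L), replace=False)) + 1
        idx.append(np.full(len(p), c))
        pos.append(p)
    return Genome(chrom_names=chrom_names,
                  chrom_lengths=list(params.chrom_lengths),
                  snp_chrom_idx=np.concatenate(idx),
                  snp_pos=np.concatenate(pos).astype(np.int64))


def _ancestral_line_freqs(params: DesignParams, S: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols line-specific frequencies around a shared ancestor."""
    p_anc = rng.uniform(0.05, 0.95, size=S)
    F = params.line_divergence
    if F <= 0:
        return np.tile(p_anc, (params.n_ancestral_lines, 1))
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    out = np.empty((params.n_ancestral_lines, S))
    for l in range(params.n_ancestral_lines):
        out[l] = np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)
    return out


def _mosaic_haplotype(genome: Genome, prototypes: np.ndarray, own_line: int,
                      params: DesignParams, rng: np.random.Generator,
                      noflip: np.ndarray | None = None) -> np.ndarray:
    """One founder haplotype as a mosaic of line-specific prototypes.

    The hidden state is a (line, prototype) pair: it starts at the
    founder's own line with a random prototype, occasionally switches
    prototype within the line (prototype_switch_rate per bp) and, more
    rarely, switches ancestral line altogether (founder_switch_rate per
    bp — old admixture among the meat lines).  Alleles are copied from
    the prototype with a small flip probability (recent mutation /
    genotyping noise).  Sharing long prototype segments is what gives
    founder haplotypes realistic LD — and gives selection a haplotype to
    sweep.
    """
    n_lines, n_proto, S = prototypes.shape
    line = np.empty(S, dtype=np.int64)
    proto = np.empty(S, dtype=np.int64)
    total_rate = params.founder_switch_rate + params.prototype_switch_rate
    p_line_switch = params.founder_switch_rate / total_rate
    for c, L in enumerate(genome.chrom_lengths):
        sl = genome.chrom_slice(c)
        pos = genome.snp_pos[sl]
        n_sw = rng.poisson(total_rate * L)
        cur_l, cur_p = own_line, int(rng.integers(n_proto))
        if n_sw == 0:
            line[sl] = cur_l
            proto[sl] = cur_p
            continue
        sw = np.sort(rng.uniform(0, L, size=n_sw))
        seg_l = [cur_l]
        seg_p = [cur_p]
        for _ in range(n_sw):
            if rng.random() < p_line_switch:
                cur_l = int(rng.integers(n_lines))
            cur_p = int(rng.integers(n_proto))
            seg_l.append(cur_l)
            seg_p.append(cur_p)
        seg = np.searchsorted(sw, pos)
        line[sl] = np.asarray(seg_l)[seg]
        proto[sl] = np.asarray(seg_p)[seg]
    hap = prototypes[line, proto, np.arange(S)].astype(np.uint8)
    flip = rng.random(S) < params.mutation_noise
    if noflip is not None:
        flip[noflip] = False
    return np.where(flip, 1 - hap, hap).astype(np.uint8)


def make_founders(params: DesignParams,
                  genome: Genome | None = None,
                  rng: np.random.Generator | None = None,
                  line_freqs: np.ndarray | None = None,
                  qtn_plant: dict | None = None) -> tuple:
    """Founder stock: 23 sires + 68 dams assigned ancestral lines round-robin.

    ``qtn_plant`` maps a SNP index to a (line, prototype) pair: the
    alternate allele at that site is carried by exactly that one prototype
    haplotype (a mutation that arose once), and the site is exempt from
    mutation noise.  Returns (genome, founders).
    """
    rng = rng or np.random.default_rng(params.seed)
    if genome is None:
        genome = make_genome(params, rng)
    n_f = params.founder_sires + params.founder_dams
    lines = np.arange(n_f) % params.n_ancestral_lines
    if line_freqs is None:
        line_freqs = _ancestral_line_freqs(params, genome.n_snps, rng)
    prototypes = (rng.random((params.n_ancestral_lines,
                              params.prototypes_per_line,
                              genome.n_snps))
                  < line_freqs[:, None, :]).astype(np.uint8)
    noflip = None
    if qtn_plant:
        noflip = np.fromiter(qtn_plant.keys(), dtype=np.int64)
        for qi, (l, pr) in qtn_plant.items():
            prototypes[:, :, qi] = 0
            prototypes[l, pr, qi] = 1
    haps = np.empty((n_f, 2, genome.n_snps), dtype=np.uint8)
    for i in range(n_f):
        for h in range(2):
            haps[i, h] = _mosaic_haplotype(genome, prototypes, lines[i],
                                           params, rng, noflip=noflip)
    is_male = np.zeros(n_f, dtype=bool)
    is_male[:params.founder_sires] = True
    return genome, Founders(haplotypes=haps, lines=lines, is_male=is_male,
                            line_freqs=line_freqs)


# --------------------------------------------------------------------------
# meiosis and generations

def meiosis(hap0: np.ndarray, hap1: np.ndarray, genome: Genome,
            recomb_rate: float, rng: np.random.Generator,
            return_crossovers: bool = False):
    """One gamete: crossovers Poisson(recomb_rate * L) per chromosome."""
    gamete = np.empty_like(hap0)
    crossovers = []
    for c, L in enumerate(genome.chrom_lengths):
        sl = genome.chrom_slice(c)
        pos = genome.snp_pos[sl]
        n_xo = rng.poisson(recomb_rate * L)
        start = int(rng.integers(2))
        if n_xo == 0:
            gamete[sl] = hap0[sl] if start == 0 else hap1[sl]
            crossovers.append((start, np.empty(0)))
            continue
        xo = np.sort(rng.uniform(0, L, size=n_xo))
        phase = (start + np.searchsorted(xo, pos)) % 2
        gamete[sl] = np.where(phase == 0, hap0[sl], hap1[sl])
        crossovers.append((start, xo))
    if return_crossovers:
        return gamete, crossovers
    return gamete


def _breed(sire_haps, dam_haps, n_off, genome, params, rng):
    """n_off offspring from random sire x dam matings."""
    ns, nd = sire_haps.shape[0], dam_haps.shape[0]
    out = np.empty((n_off, 2, genome.n_snps), dtype=np.uint8)
    for i in range(n_off):
        s = int(rng.integers(ns))
        d = int(rng.integers(nd))
        out[i, 0] = meiosis(sire_haps[s, 0], sire_haps[s, 1], genome,
                            params.recomb_rate, rng)
        out[i, 1] = meiosis(dam_haps[d, 0], dam_haps[d, 1], genome,
                            params.recomb_rate, rng)
    return out


def _genotypic_value(haps: np.ndarray, qtn_idx: np.ndarray,
                     effects: np.ndarray) -> np.ndarray:
    dos = haps[:, 0, qtn_idx].astype(np.float64) + haps[:, 1, qtn_idx]
    return dos @ effects


def simulate_design(params: DesignParams,
                    vcf_path: str | Path | None = None) -> tuple:
    """Run the full breeding design; returns (GenotypeMatrix, SimulationTruth).

    Selection is strict truncation on phenotype within sex: the
    up-selected line A keeps the highest-ranking candidates, the
    down-selected line B the lowest.  Maintenance generations use random
    parents.  F1s are crosses of final-generation line-A sires with
    line-B dams.  Only SNPs segregating among the sampled birds are
    emitted (sequencing discovers variants in the sample).
    """
    rng = np.random.default_rng(params.seed)
    genome = make_genome(params, rng)
    S = genome.n_snps

    # QTNs: each favourable allele arose once, on a single prototype
    # haplotype of one ancestral line — so selection sweeps that haplotype
    # and leaves the local signature a haplotype-differentiation scan is
    # built to see.  (A variant at intermediate frequency on many founder
    # backgrounds would give a signature-less soft sweep.)  QTNs sit in
    # the central part of a chromosome, one per chromosome while possible.
    central = np.zeros(S, dtype=bool)
    for c, L in enumerate(genome.chrom_lengths):
        sl = genome.chrom_slice(c)
        pos = genome.snp_pos[sl]
        central[sl] = (pos > 0.2 * L) & (pos < 0.8 * L)
    qtn_idx = []
    chroms = rng.permutation(len(genome.chrom_lengths))
    for j in range(params.n_qtn):
        c = chroms[j % len(chroms)]
        cand = np.flatnonzero(central & (genome.snp_chrom_idx == c))
        if len(cand) == 0:
            raise ValueError("no eligible QTN position on chromosome")
        qtn_idx.append(int(rng.choice(cand)))
    qtn_idx = np.sort(np.asarray(qtn_idx, dtype=np.int64))
    plant = {int(qi): (int(rng.integers(params.n_ancestral_lines)),
                       int(rng.integers(params.prototypes_per_line)))
             for qi in qtn_idx}
    genome, founders = make_founders(params, genome=genome, rng=rng,
                                     qtn_plant=plant)
    effects = np.asarray(params.qtn_effects, dtype=float)

    gv_f = _genotypic_value(founders.haplotypes, qtn_idx, effects)
    vg = gv_f.var()
    ve = vg * (1.0 - params.heritability) / params.heritability \
        if vg > 0 else 1.0
    sd_e = float(np.sqrt(ve))

    n_cand = params.candidates_per_line
    ns_gen, nd_gen = params.sires_per_generation, params.dams_per_generation
    means_rows, ped_rows = [], []

    def record(gen, line, haps, pheno=None):
        gv = _genotypic_value(haps, qtn_idx, effects)
        means_rows.append({
            "generation": gen, "line": line, "mean_gv": float(gv.mean()),
            "mean_phenotype": float(pheno.mean()) if pheno is not None
            else float(gv.mean()),
        })

    # generation 1: a common candidate pool is split into the two lines
    sire_h = founders.haplotypes[founders.is_male]
    dam_h = founders.haplotypes[~founders.is_male]
    ped_rows.append({"generation": 0, "line": "founders",
                     "n_sires": len(sire_h), "n_dams": len(dam_h)})
    pool = _breed(sire_h, dam_h, 2 * n_cand, genome, params, rng)
    gv = _genotypic_value(pool, qtn_idx, effects)
    pheno = gv + rng.normal(0.0, sd_e, size=len(gv))
    males = np.arange(len(pool)) % 2 == 0
    order_m = np.argsort(pheno[males], kind="stable")
    order_f = np.argsort(pheno[~males], kind="stable")
    m_idx = np.flatnonzero(males)[order_m]
    f_idx = np.flatnonzero(~males)[order_f]
    lines = {
        "lineA": (pool[m_idx[-ns_gen:]], pool[f_idx[-nd_gen:]]),
        "lineB": (pool[m_idx[:ns_gen]], pool[f_idx[:nd_gen]]),
    }
    for ln in lines:
        sel = np.concatenate([lines[ln][0], lines[ln][1]])
        record(1, ln, sel)
        ped_rows.append({"generation": 1, "line": ln,
                         "n_sires": ns_gen, "n_dams": nd_gen})

    # remaining selection generations: within-line truncation
    for gen in range(2, params.selection_generations + 1):
        for ln, top in (("lineA", True), ("lineB", False)):
            sh, dh = lines[ln]
            cand = _breed(sh, dh, n_cand, genome, params, rng)
            gv = _genotypic_value(cand, qtn_idx, effects)
            pheno = gv + rng.normal(0.0, sd_e, size=len(gv))
            males = np.arange(len(cand)) % 2 == 0
            om = np.argsort(pheno[males], kind="stable")
            of = np.argsort(pheno[~males], kind="stable")
            mi = np.flatnonzero(males)[om]
            fi = np.flatnonzero(~males)[of]
            if top:
                new = (cand[mi[-ns_gen:]], cand[fi[-nd_gen:]])
            else:
                new = (cand[mi[:ns_gen]], cand[fi[:nd_gen]])
            lines[ln] = new
            record(gen, ln, np.concatenate(new), None)
            ped_rows.append({"generation": gen, "line": ln,
                             "n_sires": ns_gen, "n_dams": nd_gen})

    # maintenance: random parents
    total_gens = params.selection_generations + params.maintenance_generations
    for gen in range(params.selection_generations + 1, total_gens + 1):
        for ln in lines:
            sh, dh = lines[ln]
            new_s = _breed(sh, dh, ns_gen, genome, params, rng)
            new_d = _breed(sh, dh, nd_gen, genome, params, rng)
            lines[ln] = (new_s, new_d)
            record(gen, ln, np.concatenate([new_s, new_d]))
            ped_rows.append({"generation": gen, "line": ln,
                             "n_sires": ns_gen, "n_dams": nd_gen})

    # sampling and F1 production
    a_s, a_d = lines["lineA"]
    b_s, b_d = lines["lineB"]
    a_pool = np.concatenate([a_s, a_d])
    b_pool = np.concatenate([b_s, b_d])
    sa = rng.choice(len(a_pool), size=params.n_sample_a, replace=False)
    sb = rng.choice(len(b_pool), size=params.n_sample_b, replace=False)
    f1 = _breed(a_s, b_d, params.n_sample_f1, genome, params, rng)

    sampled = np.concatenate([a_pool[sa], b_pool[sb], f1])
    ids = ([f"A{i + 1}" for i in range(params.n_sample_a)]
           + [f"B{i + 1}" for i in range(params.n_sample_b)]
           + [f"F1_{i + 1}" for i in range(params.n_sample_f1)])
    pops = (["lineA"] * params.n_sample_a + ["lineB"] * params.n_sample_b
            + ["F1"] * params.n_sample_f1)
    dosage = (sampled[:, 0, :].astype(np.int8) + sampled[:, 1, :])

    seg = (dosage.sum(axis=0) > 0) & (dosage.sum(axis=0) < 2 * len(ids))
    keep = np.flatnonzero(seg)
    g = GenotypeMatrix(
        individuals=np.array(ids, dtype=object),
        populations=np.array(pops, dtype=object),
        chrom=np.array([genome.chrom_names[c]
                        for c in genome.snp_chrom_idx[keep]], dtype=object),
        pos=genome.snp_pos[keep],
        ref=np.array(["A"] * len(keep), dtype=object),
        alt=np.array(["G"] * len(keep), dtype=object),
        dosage=dosage[:, keep],
    )

    qtn_rows = []
    if len(qtn_idx):
        for ln, pool_h in (("lineA", a_pool), ("lineB", b_pool)):
            freqs = pool_h[:, :, qtn_idx].reshape(-1, len(qtn_idx)).mean(axis=0)
            for j, f in enumerate(freqs):
                qtn_rows.append({"line": ln, "qtn": j, "alt_freq": float(f)})

    truth = SimulationTruth(
        qtn_snp_index=qtn_idx,
        qtn_chrom=[genome.chrom_names[c] for c in genome.snp_chrom_idx[qtn_idx]],
        qtn_pos=genome.snp_pos[qtn_idx],
        qtn_effects=effects,
        line_means=pd.DataFrame(means_rows),
        qtn_freqs=pd.DataFrame(qtn_rows),
        pedigree=pd.DataFrame(ped_rows),
        genome=genome,
        sampled_snp_index=keep,
    )
    if vcf_path is not None:
        write_vcf(g, vcf_path,
                  chrom_sizes=dict(zip(genome.chrom_names,
                                       genome.chrom_lengths)))
    return g, truth


def effective_size(params: DesignParams) -> float:
    """Harmonic-mean effective size from per-generation parent counts."""
    nes = []
    nm, nf = params.founder_sires, params.founder_dams
    nes.append(4.0 * nm * nf / (nm + nf))
    total = params.selection_generations + params.maintenance_generations
    nm, nf = params.sires_per_generation, params.dams_per_generation
    nes.extend([4.0 * nm * nf / (nm + nf)] * total)
    return len(nes) / np.sum(1.0 / np.asarray(nes))


# --------------------------------------------------------------------------
# fixtures

def make_fixtures(truth: SimulationTruth, params: DesignParams,
                  seed: int = 0,
                  imbalance_odds: float = 0.6,
                  ase_depth: int = 500,
                  n_ase_individuals: int = 5,
                  ase_replicates: int = 2,
                  ct_shift: float = 1.4,
                  ct_sd: float = 0.4,
                  n_ct_per_line: int = 12,
                  gene_length: int = 20_000,
                  gene_spacing: int = 250_000,
                  qtl_halfwidth: int = 6_000_000) -> Fixtures:
    """Companion fixtures: toy genes, QTL intervals, ASE counts, Ct tables.

    Toy genes tile every chromosome (one gene forced across each QTN); QTL
    intervals span +-6 Mb around each QTN (matching linkage-mapping
    resolution of ~12 Mb intervals); cDNA pyrosequencing counts are
    binomial around a programmable allelic imbalance (default odds 0.6)
    with gDNA balanced; Ct tables carry a between-line shift on the target
    gene (default 1.4 cycles, i.e. fold ~2.6).
    """
    rng = np.random.default_rng(seed)
    genome = truth.genome

    gene_rows = []
    gid = 0
    for c, L in enumerate(genome.chrom_lengths):
        start = gene_spacing // 2
        while start + gene_length <= L:
            gene_rows.append({"gene_id": f"gene{gid}",
                              "chrom": genome.chrom_names[c],
                              "start": start, "end": start + gene_length - 1})
            gid += 1
            start += gene_spacing
    for chrom, pos in zip(truth.qtn_chrom, truth.qtn_pos):
        gene_rows.append({"gene_id": f"gene{gid}", "chrom": chrom,
                          "start": max(1, int(pos) - gene_length // 2),
                          "end": int(pos) + gene_length // 2})
        gid += 1
    genes = pd.DataFrame(gene_rows)

    qtls = []
    for j, (chrom, pos) in enumerate(zip(truth.qtn_chrom, truth.qtn_pos)):
        c = genome.chrom_names.index(chrom)
        L = genome.chrom_lengths[c]
        qtls.append(QTLInterval(
            id=f"QTL{j + 1}", chrom=chrom,
            start=max(1, int(pos) - qtl_halfwidth),
            end=min(L, int(pos) + qtl_halfwidth),
            significance="suggestive"))

    cdna_p = imbalance_odds * 0.5 / (imbalance_odds * 0.5 + 0.5)
    ase_rows = []
    for i in range(n_ase_individuals):
        for rep in range(ase_replicates):
            gc = rng.binomial(ase_depth, 0.5)
            cc = rng.binomial(ase_depth, cdna_p)
            gc = min(max(gc, 1), ase_depth - 1)
            cc = min(max(cc, 1), ase_depth - 1)
            ase_rows.append({
                "individual": f"F1_{i + 1}", "marker": "snp1",
                "replicate": rep,
                "gdna_ref_freq": gc / ase_depth,
                "cdna_ref_freq": cc / ase_depth,
            })
    ase = pd.DataFrame(ase_rows)

    ct_rows = []
    base = 23.5
    for ln, shift, n in (("lineA", 0.0, n_ct_per_line),
                         ("lineB", ct_shift, n_ct_per_line)):
        for i in range(n):
            ct_rows.append({
                "sample": f"{ln}_{i + 1}", "line": ln,
                "ct_target": rng.normal(base + shift, ct_sd),
                "ct_reference": rng.normal(20.0, 0.2),
            })
    ct = pd.DataFrame(ct_rows)
    return Fixtures(genes=genes, qtls=qtls, ase=ase, ct=ct)


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in genes.iterrows():
            fh.write(f"{r.chrom}\tsim\tgene\t{r.start}\t{r.end}\t.\t+\t.\t"
                     f"ID={r.gene_id}\n")


def write_qtl_bed(qtls: Sequence[QTLInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for q in qtls:
            fh.write(f"{q.chrom}\t{q.start - 1}\t{q.end}\t{q.id}\n")
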