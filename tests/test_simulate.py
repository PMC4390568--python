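import numpy as np
import pandas as pd
import pytest

from hapsweep.expression import allelic_ratio, AseSample, differential_expression, relative_expression
from hapsweep.genotypes import allele_frequencies, read_vcf
from hapsweep.kinship import reynolds_distance
from hapsweep.simulate import (DesignParams, effective_size, make_fixtures,
                               make_founders, make_genome, meiosis,
                               simulate_design, write_gff3, write_qtl_bed)

SMALL = dict(chrom_lengths=(1_500_000,), seed=7)


@pytest.fixture(scope="module")
def small_sim():
    params = DesignParams(n_qtn=1, qtn_effects=(2.0,), **SMALL)
    g, truth = simulate_design(params)
    return params, g, truth


class TestGenomeAndFounders:
    def test_snp_count_poisson(self):
        params = DesignParams(chrom_lengths=(2_000_000, 1_000_000), seed=0)
        genome = make_genome(params, np.random.default_rng(0))
        lam = 2.6 * 3000  # density * total kb
        assert abs(genome.n_snps - lam) < 5 * np.sqrt(lam)
        for c in (0, 1):
            sl = genome.chrom_slice(c)
            assert np.all(np.diff(genome.snp_pos[sl]) > 0)

    def test_founder_counts_and_determinism(self):
        params = DesignParams(chrom_lengths=(400_000,), seed=3)
        g1, f1 = make_founders(params)
        g2, f2 = make_founders(params)
        assert f1.haplotypes.shape[0] == 23 + 68
        assert f1.is_male.sum() == 23
        np.testing.assert_array_equal(f1.haplotypes, f2.haplotypes)

    def test_single_ancestral_line_unstructured(self):
        params = DesignParams(chrom_lengths=(600_000,), seed=5,
                              n_ancestral_lines=1)
        _, f = make_founders(params)
        pool = f.haplotypes.reshape(-1, f.haplotypes.shape[-1])
        rng = np.random.default_rng(0)
        split = rng.permutation(len(pool))
        pa = pool[split[:len(pool) // 2]].mean(axis=0)
        pb = pool[split[len(pool) // 2:]].mean(axis=0)
        ok = (pa > 0) | (pb > 0)
        assert reynolds_distance(pa[ok], pb[ok]) < 0.02

    def test_six_lines_are_differentiated(self):
        params = DesignParams(chrom_lengths=(600_000,), seed=5)
        _, f = make_founders(params)
        pool = f.haplotypes.mean(axis=1)
        pa = pool[f.lines == 0].mean(axis=0)
        pb = pool[f.lines == 1].mean(axis=0)
        assert reynolds_distance(pa, pb) > 0.05


class TestMeiosis:
    def test_mendelian_consistency(self, rng):
        params = DesignParams(chrom_lengths=(2_000_000,), seed=1)
        genome = make_genome(params, np.random.default_rng(1))
        S = genome.n_snps
        h0 = rng.integers(0, 2, S).astype(np.uint8)
        h1 = rng.integers(0, 2, S).astype(np.uint8)
        gam, xos = meiosis(h0, h1, genome, 5e-7, rng, return_crossovers=True)
        (start, xo) = xos[0]
        phase = (start + np.searchsorted(xo, genome.snp_pos)) % 2
        expected = np.where(phase == 0, h0, h1)
        np.testing.assert_array_equal(gam, expected)

    def test_crossover_rate(self, rng):
        params = DesignParams(chrom_lengths=(1_000_000,), seed=1)
        genome = make_genome(params, np.random.default_rng(1))
        h0 = np.zeros(genome.n_snps, dtype=np.uint8)
        h1 = np.ones(genome.n_snps, dtype=np.uint8)
        rate = 2e-6
        switches = [np.sum(np.diff(meiosis(h0, h1, genome, rate, rng)
                                   .astype(int)) != 0)
                    for _ in range(300)]
        assert np.mean(switches) == pytest.approx(rate * 1_000_000, rel=0.25)


class TestSimulateDesign:
    def test_sampled_design_shape(self, small_sim):
        _, g, truth = small_sim
        assert g.n_individuals == 20
        assert list(g.populations).count("lineA") == 4
        assert list(g.populations).count("lineB") == 7
        assert list(g.populations).count("F1") == 9
        # emitted SNPs segregate in the sample
        f = allele_frequencies(g)
        assert np.nanmax(f.maf) > 0
        assert truth.pedigree["generation"].max() == 35

    def test_trait_divergence(self, small_sim):
        _, _, truth = small_sim
        lm = truth.line_means.pivot(index="generation", columns="line",
                                    values="mean_gv")
        gap = (lm["lineA"] - lm["lineB"])
        assert gap.iloc[-1] > 0
        # divergence develops during the selection phase
        assert gap.loc[7] > gap.loc[1] - 1e-9

    def test_strong_qtn_outlier_differentiation(self, small_sim):
        _, g, truth = small_sim
        f = allele_frequencies(g)
        diff = np.abs(f.freq["lineA"] - f.freq["lineB"])
        i = np.searchsorted(g.pos, truth.qtn_pos[0])
        assert diff[i] >= np.nanquantile(diff, 0.99)

    def test_byte_identical_vcf_for_fixed_seed(self, tmp_path):
        params = DesignParams(chrom_lengths=(300_000,), seed=11)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        simulate_design(params, vcf_path=p1)
        simulate_design(params, vcf_path=p2)
        assert p1.read_bytes() == p2.read_bytes()
        pops = {f"A{i}": "lineA" for i in range(1, 5)}
        pops.update({f"B{i}": "lineB" for i in range(1, 8)})
        pops.update({f"F1_{i}": "F1" for i in range(1, 10)})
        g = read_vcf(p1, pops)
        assert g.n_individuals == 20

    def test_drift_matches_pedigree_expectation(self):
        # pure drift (no QTN): Reynolds distance between the lines within a
        # generous Monte-Carlo band of 1 - (1 - 1/(2 Ne))^T
        params = DesignParams(chrom_lengths=(800_000,), seed=21, n_qtn=0)
        g, _ = simulate_design(params)
        f = allele_frequencies(g)
        ok = np.isfinite(f.freq["lineA"]) & np.isfinite(f.freq["lineB"])
        d = reynolds_distance(f.freq["lineA"][ok], f.freq["lineB"][ok])
        ne = effective_size(params)
        expected = 1 - (1 - 1 / (2 * ne)) ** 35
        assert d == pytest.approx(expected, rel=0.5)

    def test_impossible_selection_rejected(self):
        with pytest.raises(ValueError):
            # too few male candidates to supply 60 sires
            DesignParams(selected_fraction=0.9, sires_per_generation=60,
                         dams_per_generation=10).candidates_per_line


class TestFixtures:
    def test_fixture_files_parse(self, small_sim, tmp_path):
        params, _, truth = small_sim
        fx = make_fixtures(truth, params, seed=1)
        gff = tmp_path / "genes.gff3"
        bed = tmp_path / "qtl.bed"
        write_gff3(fx.genes, gff)
        write_qtl_bed(fx.qtls, bed)
        from hapsweep.sweeps import annotate_genes, read_qtl_bed, SweepRegion
        qtls = read_qtl_bed(bed)
        assert len(qtls) == 1
        q = truth.qtn_pos[0]
        assert qtls[0].start <= q <= qtls[0].end
        # a gene is forced across the QTN
        region = [SweepRegion(truth.qtn_chrom[0], q - 1000, q + 1000, 2, 2)]
        assert annotate_genes(region, gff)[0].genes

    def test_ase_fixture_recovers_programmed_imbalance(self, small_sim):
        params, _, truth = small_sim
        fx = make_fixtures(truth, params, seed=3, imbalance_odds=0.6,
                           n_ase_individuals=5)
        samples = [AseSample(r.individual, r.marker, r.gdna_ref_freq,
                             r.cdna_ref_freq, r.replicate)
                   for r in fx.ase.itertuples()]
        ratios = [allelic_ratio(s) for s in samples]
        assert np.mean(ratios) == pytest.approx(0.6, abs=0.05)

    def test_balanced_ase_fixture_calibrated(self, small_sim):
        from hapsweep.expression import ase_test
        params, _, truth = small_sim
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            fx = make_fixtures(truth, params, seed=seed, imbalance_odds=1.0,
                               n_ase_individuals=8)
            samples = [AseSample(r.individual, r.marker, r.gdna_ref_freq,
                                 r.cdna_ref_freq, r.replicate)
                       for r in fx.ase.itertuples()]
            _, p = ase_test(samples)
            hits += p < 0.05
        assert hits / n_rep < 0.12

    def test_ct_fixture_recovers_line_shift(self, small_sim):
        params, _, truth = small_sim
        fx = make_fixtures(truth, params, seed=5, ct_shift=1.4)
        a = fx.ct[fx.ct.line == "lineA"]
        b = fx.ct[fx.ct.line == "lineB"]
        ea = relative_expression(a.ct_target, a.ct_reference)
        eb = relative_expression(b.ct_target, b.ct_reference)
        fold, _, p = differential_expression(ea, eb)
        assert fold == pytest.approx(2 ** 1.4, rel=0.35)
        assert p < 0.01
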