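import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hapsweep.sweeps import (QTLInterval, SweepRegion, annotate_genes,
                             call_sweeps, coverage_enrichment,
                             expected_sweep_size, overall_summary,
                             overlap_qtl, read_qtl_bed,
                             summarize_by_chromosome)


def scan_table(pos, q, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "q": q})


class TestCallSweeps:
    def test_no_significant_snps(self):
        t = scan_table([100, 200], [0.5, 0.9])
        assert call_sweeps(t) == []

    def test_singletons_discarded(self):
        t = scan_table([100_000, 200_000, 300_000], [0.01] * 3)
        assert call_sweeps(t, merge_gap=50_000) == []

    def test_hand_merge(self):
        pos = [10_000_000, 10_020_000, 10_040_000, 12_000_000, 12_010_000]
        t = scan_table(pos, [0.01] * 5)
        regions = call_sweeps(t, merge_gap=50_000)
        assert [(r.start, r.end, r.size_bp) for r in regions] == [
            (10_000_000, 10_040_000, 40_001),
            (12_000_000, 12_010_000, 10_001),
        ]
        assert all(r.n_snps_significant >= 2 for r in regions)

    def test_counts_all_analyzed_snps_inside(self):
        t = scan_table([100, 150, 200, 250], [0.01, 0.5, 0.01, 0.9])
        (r,) = call_sweeps(t, merge_gap=1000)
        assert (r.start, r.end) == (100, 200)
        assert r.n_snps_total == 3
        assert r.n_snps_significant == 2

    def test_input_order_invariance(self, rng):
        pos = np.sort(rng.choice(10**6, 200, replace=False))
        q = rng.uniform(0, 0.4, 200)
        t = scan_table(pos, q)
        shuffled = t.sample(frac=1, random_state=0)
        a = call_sweeps(t)
        b = call_sweeps(shuffled)
        assert [(r.start, r.end) for r in a] == [(r.start, r.end) for r in b]


GFF = """\
##gff-version 3
chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=geneA
chr1\tsrc\tgene\t5000\t9000\t.\t-\t.\tID=geneB
chr1\tsrc\tgene\t8500\t12000\t.\t+\t.\tID=geneC
chr2\tsrc\tgene\t100\t400\t.\t+\t.\tID=geneD
chr2\tsrc\tgene\t600\t900\t.\t+\t.\tID=geneE
"""


class TestAnnotateGenes:
    @pytest.fixture
    def gff(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(GFF)
        return p

    def test_partial_overlap_counts(self, gff):
        regions = [
            SweepRegion("chr1", 2500, 4000, 5, 2),      # intergenic
            SweepRegion("chr1", 1900, 1950, 3, 2),      # inside geneA
            SweepRegion("chr1", 8600, 8700, 3, 2),      # geneB and geneC
        ]
        out = annotate_genes(regions, gff)
        assert out[0].genes == []
        assert out[1].genes == ["geneA"]
        assert out[2].genes == ["geneB", "geneC"]

    def test_brute_force_recount(self, gff, rng):
        genes = [("chr1", 1000, 2000), ("chr1", 5000, 9000),
                 ("chr1", 8500, 12000), ("chr2", 100, 400),
                 ("chr2", 600, 900)]
        regions = []
        for _ in range(10):
            c = "chr1" if rng.random() < 0.5 else "chr2"
            s = int(rng.integers(1, 11_000))
            regions.append(SweepRegion(c, s, s + int(rng.integers(1, 3000)),
                                       2, 2))
        out = annotate_genes(regions, gff)
        for r in out:
            expected = sum(1 for (c, a, b) in genes
                           if c == r.chrom and a <= r.end and r.start <= b)
            assert len(r.genes) == expected


class TestSummaries:
    def test_single_region_coverage(self):
        regions = [SweepRegion("chr1", 1, 1_000_000, 10, 5)]
        df = summarize_by_chromosome(regions, {"chr1": 100_000_000})
        assert df.loc[0, "coverage_pct"] == pytest.approx(1.0)
        assert df.loc[0, "mean_kb"] == pytest.approx(1000.0)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            summarize_by_chromosome([SweepRegion("chrX", 1, 10, 2, 2)],
                                    {"chr1": 1000})

    def test_overall_roll_up(self):
        per = pd.DataFrame({
            "chrom": ["1", "2"], "chrom_size_mb": [100.0, 50.0],
            "n_sweeps": [2, 1],
            "mean_kb": [100.0, 40.0], "min_kb": [1, 1], "max_kb": [1, 1],
            "coverage_pct": [0.2, 0.08],
            "snps_mean": [500.0, 100.0], "snps_min": [1, 1],
            "snps_max": [1, 1],
            "genes_mean": [2.0, 1.0], "genes_min": [0, 0], "genes_max": [3, 1],
            "genes_total": [4, 1],
        })
        out = overall_summary(per, genome_size_mb=200.0)
        # weighted coverage: (0.2*100 + 0.08*50)/200
        assert out["coverage_pct"] == pytest.approx(0.12)
        assert out["mean_size_kb"] == pytest.approx(70.0)   # unweighted
        assert out["mean_snps_per_sweep"] == pytest.approx(300.0)
        assert out["mean_size_kb_weighted"] == pytest.approx(80.0)


class TestQtlOverlap:
    def test_inside_and_boundary(self):
        q = QTLInterval("Q1", "chr1", 1000, 2000)
        inside = SweepRegion("chr1", 1200, 1300, 2, 2)
        abutting = SweepRegion("chr1", 2001, 2100, 2, 2)
        out = overlap_qtl([inside, abutting], [q])
        assert out["Q1"] == [inside]

    def test_toy_per_qtl_counts(self):
        # sweep placement mirroring a published colocalization table:
        # 5 + 3 + 1 + 1 sweeps in four QTL
        from hapsweep.datasets import chicken_qtl_intervals, chicken_qtl_sweeps
        qtls = chicken_qtl_intervals()
        sweeps = [SweepRegion(r.chrom, r.start, r.end, 2, 2)
                  for r in chicken_qtl_sweeps().itertuples()]
        out = overlap_qtl(sweeps, qtls)
        assert [len(out[q.id]) for q in qtls] == [5, 3, 1, 1]

    def test_brute_force_all_pairs(self, rng):
        qtls = [QTLInterval(f"q{i}", "chr1", int(a), int(a) + 500)
                for i, a in enumerate(rng.choice(10**5, 5, replace=False))]
        sweeps = [SweepRegion("chr1", int(a), int(a) + 200, 2, 2)
                  for a in rng.choice(10**5, 20, replace=False)]
        out = overlap_qtl(sweeps, qtls)
        for q in qtls:
            expected = [s for s in sweeps
                        if s.start <= q.end and q.start <= s.end]
            assert out[q.id] == expected


class TestCoverageEnrichment:
    def test_hand_chi2(self):
        # genome 100 Mb, QTL 10 Mb, sweeps 1 Mb of which 0.5 Mb inside QTL
        qtl = QTLInterval("Q", "chr1", 1, 10_000_000)
        sweeps = [
            SweepRegion("chr1", 2_000_001, 2_500_000, 2, 2),    # inside
            SweepRegion("chr1", 50_000_001, 50_500_000, 2, 2),  # outside
        ]
        rep = coverage_enrichment(sweeps, [qtl], genome_size=100_000_000)
        assert rep.cov_genome == pytest.approx(0.01)
        assert rep.cov_qtl == pytest.approx(0.05)
        table = np.array([[0.5e6, 0.5e6], [9.5e6, 89.5e6]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert rep.chi2 == pytest.approx(chi2)
        assert rep.p == pytest.approx(p)

    def test_all_sweeps_inside_qtl(self):
        qtl = QTLInterval("Q", "chr1", 1, 10_000_000)
        sweeps = [SweepRegion("chr1", 100, 100_099, 2, 2)]
        rep = coverage_enrichment(sweeps, [qtl], genome_size=10**8)
        assert rep.cov_qtl == pytest.approx(100_000 / 10_000_000)
        assert rep.cov_genome == pytest.approx(100_000 / 10**8)

    def test_uniform_sweeps_not_enriched(self, rng):
        genome = 10**8
        qtls = [QTLInterval("Q", "chr1", 1, 10_000_000)]
        sweeps = [SweepRegion("chr1", int(a), int(a) + 9_999, 2, 2)
                  for a in np.sort(rng.choice(genome - 10**4, 200,
                                              replace=False))]
        rep = coverage_enrichment(sweeps, qtls, genome)
        assert rep.cov_qtl == pytest.approx(rep.cov_genome, rel=0.5)

    def test_empty_qtl_set_rejected(self):
        with pytest.raises(ValueError):
            coverage_enrichment([], [], genome_size=1000)


class TestExpectedSweepSize:
    def test_published_parameters(self):
        assert expected_sweep_size(10, 3e-8, 35) == pytest.approx(95_238, rel=1e-4)

    def test_scaling_in_n(self):
        assert expected_sweep_size(20, 3e-8, 35) == pytest.approx(
            expected_sweep_size(10, 3e-8, 35) / 2)

    def test_arithmetic(self):
        assert expected_sweep_size(20, 1e-8, 50) == pytest.approx(100_000)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            expected_sweep_size(0, 1e-8, 10)


class TestBedIO:
    def test_bed_coordinates_converted(self, tmp_path):
        p = tmp_path / "q.bed"
        p.write_text("chr1\t999\t2000\tQ1\nchr2\t0\t100\tQ2\n")
        qtls = read_qtl_bed(p)
        assert (qtls[0].start, qtls[0].end) == (1000, 2000)
        assert (qtls[1].start, qtls[1].end) == (1, 100)
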