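"""Published summary inputs from the divergent abdominal-fat chicken scan.

These are the printed per-chromosome sweep summary, the QTL/sweep
colocalization table and the variant-accounting counts from the
whole-genome resequencing study of two chicken lines divergently selected
for abdominal fat (7 selection + 28 maintenance generations; 20 birds
sequenced).  The raw sequence data are not public, so these printed
numbers serve as worked-example inputs: the roll-up arithmetic
(genome-wide coverage, mean sweep size, SNPs per sweep, call-rate and
density fractions) is recomputed from them by package functions rather
than asserted.
"""

from __future__ import annotations

import io

import pandas as pd

from .sweeps import QTLInterval

__all__ = [
    "chicken_sweep_table",
    "chicken_qtl_intervals",
    "chicken_qtl_sweeps",
    "CHICKEN_GENOME_MB",
    "CHICKEN_SNP_COUNTS",
    "CHICKEN_EXPECTED_SWEEP_PARAMS",
]

#: assembled genome size (Mb) underlying the per-chromosome summary
CHICKEN_GENOME_MB = 1050.9

#: variant-calling accounting: SNP/indel totals, full-call-rate subsets,
#: and the average per-bird SNP count
CHICKEN_SNP_COUNTS = {
    "n_snps_total": 11_847_150,
    "n_snps_full_call": 9_422_311,
    "n_indels_total": 1_090_316,
    "n_indels_full_call": 810_754,
    "snps_per_bird": 2_729_525,
}

#: haploid sample size, recombination rate (per bp per generation) and
#: total generations entering the expected sweep size 1/(n rho T)
CHICKEN_EXPECTED_SWEEP_PARAMS = {"n": 10, "rho": 3e-8, "T": 35}

_SWEEP_TABLE_TSV = """\
chrom	chrom_size_mb	n_sweeps	mean_kb	min_kb	max_kb	coverage_pct	snps_mean	snps_min	snps_max	genes_mean	genes_min	genes_max	genes_total
1	200.99	36	127.28	1.74	789.46	2.22	1348.37	18	10096	1.69	0	8	61
2	154.87	25	89.55	0.08	505.77	1.45	787.00	5	5238	1.64	0	13	41
3	113.66	17	93.20	0.22	535.04	1.23	943.65	9	5336	1.47	0	6	25
4	94.23	21	124.44	0.75	754.56	2.91	1324.00	16	7583	2.71	0	32	57
5	62.24	1	1.29	1.29	1.29	0.002	16.00	16	16	1.00	1	1	1
6	37.40	5	41.12	17.31	74.93	0.55	409.00	201	961	2.00	0	5	10
7	38.38	3	272.65	206.99	393.85	2.13	2724.70	2530	3019	2.67	2	4	8
8	30.67	1	103.19	103.19	103.19	0.34	570.00	570	570	2.00	2	2	2
10	22.56	6	11.04	0.10	46.48	0.29	142.00	7	555	2.17	1	6	13
11	21.93	5	303.97	10.10	1018.14	6.93	1623.60	86	4532	3.00	0	5	15
12	20.54	1	15.86	15.86	15.86	0.08	94.00	94	94	0.00	0	0	0
13	18.91	1	0.01	0.01	0.01	0.00	2.00	2	2	1.00	1	1	1
14	15.82	4	112.17	22.41	166.90	2.84	762.75	186	1620	5.00	4	6	20
17	11.18	1	107.06	107.06	107.06	0.96	650.00	650	650	1.00	1	1	1
20	13.99	1	151.00	151.00	151.00	1.08	1895.00	1895	1895	6.00	6	6	6
24	6.40	1	6.81	6.81	6.81	0.11	114.00	114	114	1.00	1	1	1
"""

_QTL_TSV = """\
id	chrom	start_mb	end_mb	significance
AF3.I	3	18.61	32.15	suggestive
AF3.II	3	39.74	48.52	suggestive
AF5	5	54.52	62.03	1%
AF7	7	4.21	17.63	suggestive
"""

# sweeps printed inside the colocalization table (start/end in Mb)
_QTL_SWEEP_TSV = """\
id	chrom	start_mb	end_mb
AF3.I-a	3	22.00	22.50
AF3.I-b	3	24.03	24.16
AF3.I-c	3	24.30	24.64
AF3.I-d	3	26.05	26.10
AF3.I-e	3	30.52	30.59
AF3.II-a	3	40.28	40.30
AF3.II-b	3	44.03	44.04
AF3.II-c	3	46.57	46.60
AF5	5	54.65	54.654
AF7	7	5.31	5.52
"""


def chicken_sweep_table() -> pd.DataFrame:
    """Printed per-chromosome sweep summary (16 chromosomes with sweeps)."""
    return pd.read_csv(io.StringIO(_SWEEP_TABLE_TSV), sep="\t",
                       dtype={"chrom": str})


def chicken_qtl_intervals() -> list:
    """The four abdominal-fat QTL colocalizing with sweeps (1-based bp)."""
    df = pd.read_csv(io.StringIO(_QTL_TSV), sep="\t", dtype={"chrom": str})
    return [QTLInterval(id=r.id, chrom=r.chrom,
                        start=int(r.start_mb * 1e6), end=int(r.end_mb * 1e6),
                        significance=r.significance)
            for r in df.itertuples()]


def chicken_qtl_sweeps() -> pd.DataFrame:
    """Sweep intervals printed in the QTL colocalization table (bp)."""
    df = pd.read_csv(io.StringIO(_QTL_SWEEP_TSV), sep="\t",
                     dtype={"chrom": str})
    df["start"] = (df.pop("start_mb") * 1e6).astype(int)
    df["end"] = (df.pop("end_mb") * 1e6).astype(int)
    return df


def snp_accounting(counts: dict | None = None,
                   genome_mb: float = CHICKEN_GENOME_MB) -> dict:
    """Call-rate fractions and per-bird SNP density from raw counts.

    Returns percentages (full-call-rate SNP and indel fractions) and the
    per-bird SNP density in SNPs per kb over the assembled genome.
    """
    c = counts or CHICKEN_SNP_COUNTS
    return {
        "snp_full_call_pct": 100.0 * c["n_snps_full_call"] / c["n_snps_total"],
        "indel_full_call_pct": 100.0 * c["n_indels_full_call"]
        / c["n_indels_total"],
        "snp_per_kb_per_bird": c["snps_per_bird"] / (genome_mb * 1e3),
    }


__all__.append("snp_accounting")
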