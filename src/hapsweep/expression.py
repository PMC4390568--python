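"""Expression evidence: ΔCt differential expression, tissue profiling,
allele-specific expression (ASE) ratios and imbalance tests.

qPCR expression is quantified as 2^-ΔCt relative to a reference gene; line
differences are tested with an unpaired Student t-test on the 2^-ΔCt
values.  ASE in heterozygous F1 individuals is quantified from
pyrosequencing allele frequencies as the cDNA reference/alternative odds
standardized by the matching gDNA odds (which should be balanced, so any
assay skew cancels); deviation of the ratio from 1 is tested
nonparametrically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CT_EXCLUSION_THRESHOLD",
    "AseSample",
    "relative_expression",
    "differential_expression",
    "tissue_profile",
    "allelic_ratio",
    "ase_test",
    "ase_test_two_sample",
    "expression_phenotype_correlation",
]

#: tissues/samples with a target Ct above this are treated as not expressed
CT_EXCLUSION_THRESHOLD = 30.0


@dataclass
class AseSample:
    """One pyrosequencing measurement of a heterozygous individual."""

    individual: str
    marker: str
    gdna_ref_freq: float
    cdna_ref_freq: float
    replicate: int = 0

    def __post_init__(self) -> None:
        for name in ("gdna_ref_freq", "cdna_ref_freq"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(
                    f"{name}={v}: frequencies must lie strictly in (0, 1) "
                    "(individual must be heterozygous)")


def relative_expression(ct_target, ct_reference):
    """Expression relative to the reference gene: 2^-(Ct_target - Ct_ref)."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    return 2.0 ** -(ct_target - ct_reference)


def differential_expression(expr_a, expr_b) -> tuple:
    """Fold change mean(A)/mean(B) and an unpaired two-tailed t-test.

    Intended for 2^-ΔCt values.  Two identical zero-variance groups give
    p = 1 by convention.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("at least two samples per group required")
    fold = a.mean() / b.mean()
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return float(fold), 0.0, 1.0
        return float(fold), float("inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(fold), float(t), float(p)


def tissue_profile(ct_by_tissue: Mapping[str, Sequence[float]],
                   threshold: float = CT_EXCLUSION_THRESHOLD) -> pd.DataFrame:
    """Fold change per tissue relative to the lowest-expressing tissue.

    Tissues with mean target Ct above ``threshold`` are excluded (treated
    as not expressed).  The reference tissue is the retained tissue with
    the maximal mean Ct; folds are 2^(Ct_ref - Ct_tissue) >= 1.
    """
    means = {t: float(np.mean(v)) for t, v in ct_by_tissue.items()}
    retained = {t: m for t, m in means.items() if m <= threshold}
    excluded = sorted(set(means) - set(retained))
    if excluded:
        logger.info("tissue_profile: excluded (Ct > %.0f): %s",
                    threshold, ", ".join(excluded))
    if not retained:
        logger.warning("tissue_profile: all tissues excluded")
        return pd.DataFrame(columns=["tissue", "mean_ct", "fold"])
    ref_ct = max(retained.values())
    rows = [{"tissue": t, "mean_ct": m, "fold": 2.0 ** (ref_ct - m)}
            for t, m in retained.items()]
    return pd.DataFrame(rows).sort_values("fold", ascending=False,
                                          ignore_index=True)


def allelic_ratio(sample: AseSample) -> float:
    """gDNA-standardized allelic ratio: odds(cDNA ref) / odds(gDNA ref).

    Equals 1 under perfectly balanced expression regardless of any
    multiplicative assay skew common to the gDNA and cDNA measurements.
    """
    c = sample.cdna_ref_freq
    g = sample.gdna_ref_freq
    return (c / (1.0 - c)) / (g / (1.0 - g))


def _average_replicates(samples: Sequence[AseSample]) -> np.ndarray:
    """Per-individual/marker mean allelic ratio (duplicates averaged)."""
    df = pd.DataFrame({
        "key": [(s.individual, s.marker) for s in samples],
        "ratio": [allelic_ratio(s) for s in samples],
    })
    return df.groupby("key")["ratio"].mean().to_numpy()


def ase_test(ratios_or_samples, average_replicates: bool = True) -> tuple:
    """Test allelic imbalance: are the ratios centred at 1?

    One-sample Wilcoxon signed-rank of log(ratio) against 0, two-tailed,
    exact for n <= 25.  Accepts either an array of ratios or a sequence
    of :class:`AseSample` (replicates averaged per individual/marker by
    default).  Returns (median ratio, p).
    """
    if len(ratios_or_samples) and isinstance(ratios_or_samples[0], AseSample):
        if average_replicates:
            ratios = _average_replicates(ratios_or_samples)
        else:
            ratios = np.array([allelic_ratio(s) for s in ratios_or_samples])
    else:
        ratios = np.asarray(ratios_or_samples, dtype=float)
    if len(ratios) < 3:
        raise ValueError("at least three ratios required")
    logr = np.log(ratios)
    if np.all(logr == 0):
        return 1.0, 1.0
    method = "exact" if len(logr) <= 25 else "auto"
    res = stats.wilcoxon(logr, alternative="two-sided", method=method,
                         zero_method="wilcox")
    return float(np.median(ratios)), float(res.pvalue)


def ase_test_two_sample(cdna_freqs, gdna_freqs) -> float:
    """Alternative mode: Mann-Whitney of cDNA vs gDNA reference odds."""
    c = np.asarray(cdna_freqs, dtype=float)
    g = np.asarray(gdna_freqs, dtype=float)
    res = stats.mannwhitneyu(c / (1 - c), g / (1 - g),
                             alternative="two-sided")
    return float(res.pvalue)


def expression_phenotype_correlation(expr, pheno) -> tuple:
    """Pearson correlation between expression and a quantitative trait."""
    x = np.asarray(expr, dtype=float)
    y = np.asarray(pheno, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("paired samples with n >= 3 required")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
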