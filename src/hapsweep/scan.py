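"""hapFLK genome scan: statistic, fit averaging, null fit, p- and q-values.

hapFLK extends the single-SNP FLK test to haplotype-cluster frequencies:
at every SNP the vector of per-population cluster frequencies is compared
with its drift expectation around the estimated ancestral cluster
frequencies, standardized by the kinship matrix (between populations) and
the multinomial covariance (between clusters).  Because cluster labels are
arbitrary and EM fits are multi-modal, the statistic — which is label
invariant — is averaged over independent EM fits.

Significance is calibrated empirically: genome-wide hapFLK values are
dominated by neutral SNPs, so a scaled chi-square null a*chi2_d is fitted
robustly (median/MAD matching, insensitive to the selected outliers),
p-values come from its upper tail and q-values from the Storey FDR
procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .cluster import ClusterConfig, HaplotypeClusterModel, cluster_frequencies
from .genotypes import GenotypeMatrix
from .kinship import KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "ScanResult",
    "hapflk_statistic",
    "HapFLKScan",
    "scan",
    "fit_null",
    "pvalues",
    "qvalues",
]

_PINV_RCOND = 1e-10


@dataclass
class ScanConfig:
    q_threshold: float = 0.1
    lambda_storey: float = 0.5
    robust_trim: tuple = (0.05, 0.95)
    null_method: str = "median_mad"  # or "trimmed_ml"

    def __post_init__(self) -> None:
        for v in (self.q_threshold, self.lambda_storey):
            if not 0.0 < v < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class ScanResult:
    """Per-SNP averaged hapFLK with fitted null parameters.

    ``table`` has columns chrom, pos, hapflk, p, q.
    """

    table: pd.DataFrame
    null_scale: float
    null_df: float
    pi0: float
    n_fits: int
    per_fit: np.ndarray | None = field(default=None, repr=False)


def _p0_clusters(P: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Ancestral cluster frequencies: per-cluster GLS, then renormalized."""
    ones = np.ones(F.shape[0])
    w = np.linalg.solve(F, ones)
    p0 = (w @ P) / w.sum()
    p0 = np.clip(p0, 0.0, 1.0)
    tot = p0.sum()
    if tot > 0:
        p0 = p0 / tot
    return p0


def hapflk_statistic(P: np.ndarray, kin: KinshipMatrix) -> float:
    """hapFLK at one SNP from per-population cluster frequencies.

    P : (J, K) array, each row on the K-simplex.  The statistic is
    d' (F kron B0)^+ d with d = vec(P - 1 p0'), B0 = diag(p0) - p0 p0'
    and a Moore-Penrose pseudo-inverse absorbing the simplex constraint
    (and any boundary p0 entries).  Invariant to cluster relabeling.
    """
    P = np.asarray(P, dtype=float)
    F = kin.F
    p0 = _p0_clusters(P, F)
    B0 = np.diag(p0) - np.outer(p0, p0)
    d = (P - p0[None, :]).ravel()  # population-major blocks, matches kron(F, B0)
    # pinv(F kron B0) = pinv(F) kron pinv(B0)
    sigma_pinv = np.kron(np.linalg.pinv(F, rcond=_PINV_RCOND),
                         np.linalg.pinv(B0, rcond=_PINV_RCOND))
    return float(max(d @ sigma_pinv @ d, 0.0))


class HapFLKScan(BaseEstimator):
    """Averaged multi-fit hapFLK scan with empirical null calibration.

    Parameters mirror :class:`ClusterConfig` plus the significance
    settings of :class:`ScanConfig`.  ``fit`` expects a MAF-filtered,
    subsampled :class:`GenotypeMatrix` (F1 individuals included — they
    inform cluster inference) and a kinship matrix estimated from the F0
    populations.

    Attributes
    ----------
    hapflk_ : (S,) ndarray       mean statistic over EM fits
    per_fit_ : (n_fits, S)       per-fit statistics (diagnostics)
    pvalues_, qvalues_ : (S,)    empirical-null tail probabilities / FDR
    null_scale_, null_df_ : float   fitted a, d of the a*chi2_d null
    pi0_ : float                 Storey estimate of the null proportion
    """

    def __init__(self, n_clusters: int = 6, n_fits: int = 10,
                 em_iterations: int = 25, random_state: int = 0,
                 q_threshold: float = 0.1, lambda_storey: float = 0.5,
                 null_method: str = "median_mad"):
        self.n_clusters = n_clusters
        self.n_fits = n_fits
        self.em_iterations = em_iterations
        self.random_state = random_state
        self.q_threshold = q_threshold
        self.lambda_storey = lambda_storey
        self.null_method = null_method

    def fit(self, X: GenotypeMatrix, y=None, kin: KinshipMatrix = None):
        if kin is None:
            raise ValueError("a KinshipMatrix is required (kin=...)")
        g = X
        f0 = kin.labels
        values = np.zeros((self.n_fits, g.n_snps))
        for fi in range(self.n_fits):
            model = HaplotypeClusterModel(
                n_clusters=self.n_clusters, n_iter=self.em_iterations,
                random_state=self.random_state, fit_index=fi,
            ).fit(g)
            freqs = cluster_frequencies(model.memberships_, g.populations, f0)
            stacked = np.stack([freqs[p] for p in f0], axis=1)  # (S, J, K)
            for s in range(g.n_snps):
                values[fi, s] = hapflk_statistic(stacked[s], kin)
        self.per_fit_ = values
        self.hapflk_ = values.mean(axis=0)
        scfg = ScanConfig(q_threshold=self.q_threshold,
                          lambda_storey=self.lambda_storey,
                          null_method=self.null_method)
        self.null_scale_, self.null_df_ = fit_null(self.hapflk_, scfg)
        self.pvalues_ = pvalues(self.hapflk_, self.null_scale_, self.null_df_)
        self.qvalues_, self.pi0_ = qvalues(self.pvalues_, scfg)
        self.chrom_ = g.chrom
        self.pos_ = g.pos
        return self

    def result(self) -> ScanResult:
        table = pd.DataFrame({
            "chrom": self.chrom_, "pos": self.pos_, "hapflk": self.hapflk_,
            "p": self.pvalues_, "q": self.qvalues_,
        })
        return ScanResult(table=table, null_scale=self.null_scale_,
                          null_df=self.null_df_, pi0=self.pi0_,
                          n_fits=self.n_fits, per_fit=self.per_fit_)


def scan(g: GenotypeMatrix, kin: KinshipMatrix,
         ccfg: ClusterConfig | None = None,
         scfg: ScanConfig | None = None) -> ScanResult:
    """Functional wrapper: multi-fit averaged hapFLK with p- and q-values."""
    ccfg = ccfg or ClusterConfig()
    scfg = scfg or ScanConfig()
    est = HapFLKScan(
        n_clusters=ccfg.K, n_fits=ccfg.n_fits,
        em_iterations=ccfg.em_iterations, random_state=ccfg.seed,
        q_threshold=scfg.q_threshold, lambda_storey=scfg.lambda_storey,
        null_method=scfg.null_method,
    ).fit(g, kin=kin)
    return est.result()


def _chi2_mad(d: float) -> float:
    """Median absolute deviation of chi2_d (numerical)."""
    m = stats.chi2.ppf(0.5, d)

    def cover(t):
        lo = max(m - t, 0.0)
        return stats.chi2.cdf(m + t, d) - stats.chi2.cdf(lo, d) - 0.5

    # mass concentrates near 0 for small d, so bracket from (almost) zero
    hi = stats.chi2.ppf(0.999999, d) + 1.0
    return brentq(cover, 1e-300, hi)


def fit_null(values: np.ndarray, cfg: ScanConfig | None = None) -> tuple:
    """Fit the neutral distribution a * chi2_d to genome-wide statistics.

    Median/MAD matching: solve MAD(values)/median(values) =
    MAD(chi2_d)/median(chi2_d) for d, then a = median(values)/median(chi2_d).
    Median and MAD ignore the upper tail, so the handful of selected
    outliers is automatically down-weighted.  A trimmed maximum-likelihood
    variant on the central quantile band is available via
    ``cfg.null_method = "trimmed_ml"``.
    """
    cfg = cfg or ScanConfig()
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 1000:
        logger.warning("fit_null: only %d values; null fit may be unstable",
                       len(v))
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad <= 0 or med <= 0:
        raise ValueError("degenerate statistic distribution (MAD or median 0)")
    if cfg.null_method == "trimmed_ml":
        return _fit_null_trimmed_ml(v, cfg)
    target = mad / med

    def gap(d):
        return _chi2_mad(d) / stats.chi2.ppf(0.5, d) - target

    lo, hi = 1e-2, 1e2
    while gap(hi) > 0 and hi < 1e6:
        hi *= 10
    while gap(lo) < 0 and lo > 1e-8:
        lo /= 10
    d = brentq(gap, lo, hi)
    a = med / stats.chi2.ppf(0.5, d)
    return float(a), float(d)


def _fit_null_trimmed_ml(v: np.ndarray, cfg: ScanConfig) -> tuple:
    from scipy.optimize import minimize

    qlo, qhi = np.quantile(v, cfg.robust_trim)
    core = v[(v >= qlo) & (v <= qhi)]

    def nll(x):
        a, d = np.exp(x)
        return -stats.chi2.logpdf(core / a, d).sum() + len(core) * np.log(a)

    res = minimize(nll, x0=np.log([1.0, max(np.median(core), 0.5)]),
                   method="Nelder-Mead")
    a, d = np.exp(res.x)
    return float(a), float(d)


def pvalues(values: np.ndarray, a: float, d: float) -> np.ndarray:
    """Upper-tail probability of a*chi2_d at each statistic value."""
    return stats.chi2.sf(np.asarray(values, dtype=float) / a, d)


def qvalues(p: np.ndarray, cfg: ScanConfig | None = None) -> tuple:
    """Storey q-values and the estimated null proportion pi0.

    pi0 = min(1, #{p > lambda} / ((1 - lambda) m)); q_(i) is the step-up
    running minimum of pi0 * m * p_(i) / i.
    """
    cfg = cfg or ScanConfig()
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    lam = cfg.lambda_storey
    pi0 = min(1.0, np.sum(p > lam) / ((1.0 - lam) * m))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, float(pi0)
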