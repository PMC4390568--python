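"""Haplotype-cluster model for unphased genotypes (fastPHASE-style).

Clusters act as local "ancestral haplotypes": at every SNP each of an
individual's two chromosomes belongs to one of K clusters, and local
linkage disequilibrium is captured by cluster membership changing slowly
along the chromosome.  The model is fitted by EM (Baum-Welch) directly on
genotypes — no phasing step — by treating the hidden state as an
unordered cluster pair.  F1 crosses can be included in the fit to sharpen
haplotype inference even though they are excluded from population
frequencies downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import _hmm
from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "ClusterConfig",
    "HaplotypeClusterModel",
    "init_params",
    "cluster_frequencies",
    "genotype_forward_backward",
]

#: physical-distance scale (bp) for the initial jump probability
#: r_s = 1 - exp(-d_s / JUMP_SCALE_BP)
JUMP_SCALE_BP = 50_000.0

#: floor/ceiling keeping emission probabilities away from {0, 1}
THETA_FLOOR = 1e-3

_ALPHA_PSEUDOCOUNT = 1e-6


@dataclass
class ClusterConfig:
    """Cluster-model settings.

    K defaults to 6, matching a founder stock mixed from six ancestral
    lines; n_fits independent EM runs are averaged downstream (the
    statistic, not the parameters, is averaged, so cluster labels need no
    alignment across fits).
    """

    K: int = 6
    n_fits: int = 10
    em_iterations: int = 25
    seed: int = 0
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_fits < 1:
            raise ValueError("K and n_fits must be >= 1")


def init_params(cfg: ClusterConfig, positions: np.ndarray, fit_index: int):
    """Initial (theta, alpha, r) for one EM fit.

    alpha is uniform; theta is drawn Uniform(0.05, 0.95) from a stream
    seeded by (seed, fit_index); r is set from physical inter-SNP distance
    d as 1 - exp(-d / 50 kb), so co-located SNPs get r = 0.
    """
    positions = np.asarray(positions, dtype=np.int64)
    S, K = len(positions), cfg.K
    rng = np.random.default_rng([cfg.seed, fit_index])
    theta = rng.uniform(0.05, 0.95, size=(S, K))
    alpha = np.full((S, K), 1.0 / K)
    r = np.zeros(S)
    if S > 1:
        d = np.diff(positions).astype(float)
        d[d < 0] = JUMP_SCALE_BP  # chromosome break: independent restart
        r[1:] = 1.0 - np.exp(-d / JUMP_SCALE_BP)
    return theta, alpha, r


class HaplotypeClusterModel(BaseEstimator):
    """EM-fitted haplotype-cluster HMM on unphased genotypes.

    Parameters
    ----------
    n_clusters : int
        Number of haplotype clusters K.
    n_iter : int
        Baum-Welch iterations.
    tol : float
        Relative log-likelihood change for early stopping.
    random_state : int
        Seed of the initialization stream.
    fit_index : int
        Index of this fit within a multi-start ensemble; (random_state,
        fit_index) determines the initialization.

    Attributes
    ----------
    theta_ : (S, K) ndarray
        Alternate-allele emission probability per SNP and cluster.
    alpha_ : (S, K) ndarray
        Local cluster weights (each row on the simplex).
    rho_ : (S,) ndarray
        Per-interval jump probabilities (rho_[0] unused).
    loglik_ : float
        Final training log-likelihood.
    loglik_history_ : list of float
        Log-likelihood before each parameter update (non-decreasing up to
        numerical tolerance).
    memberships_ : (N, S, K) ndarray
        Expected cluster counts (in [0, 2]) for the training individuals
        under the final parameters.
    """

    def __init__(self, n_clusters: int = 6, n_iter: int = 25,
                 tol: float = 1e-6, random_state: int = 0,
                 fit_index: int = 0):
        self.n_clusters = n_clusters
        self.n_iter = n_iter
        self.tol = tol
        self.random_state = random_state
        self.fit_index = fit_index

    # -- helpers -------------------------------------------------------
    @staticmethod
    def _as_dosage(X) -> np.ndarray:
        if isinstance(X, GenotypeMatrix):
            X = X.dosage
        X = np.asarray(X)
        if np.issubdtype(X.dtype, np.floating):
            X = np.where(np.isnan(X), MISSING, X)
        X = X.astype(np.int8)
        if X.ndim != 2:
            raise ValueError("genotypes must be a 2-D (individuals x SNPs) array")
        return np.ascontiguousarray(X)

    def _positions(self, X, positions) -> np.ndarray:
        if positions is None:
            if isinstance(X, GenotypeMatrix):
                # offset chromosomes so inter-chromosome gaps break LD
                return _genome_positions(X)
            return np.arange(np.shape(X)[-1], dtype=np.int64) * 1000
        return np.asarray(positions, dtype=np.int64)

    # -- estimator API -------------------------------------------------
    def fit(self, X, y=None, positions=None):
        """Fit the model to dosages X ((N, S) array or GenotypeMatrix)."""
        G = self._as_dosage(X)
        if G.shape[0] < 2:
            raise ValueError("at least two individuals required")
        if G.shape[1] < 1:
            raise ValueError("empty genotype matrix")
        pos = self._positions(X, positions)
        cfg = ClusterConfig(K=self.n_clusters, em_iterations=self.n_iter,
                            seed=self.random_state,
                            convergence_tol=self.tol)
        theta, alpha, r = init_params(cfg, pos, self.fit_index)
        N, S = G.shape
        K = self.n_clusters
        memb = np.empty((N, S, K))
        history: list[float] = []
        for _ in range(self.n_iter):
            th_num = np.zeros((S, K))
            th_den = np.zeros((S, K))
            a_num = np.zeros((S, K))
            jmp = np.zeros(S)
            ll = _hmm.estep(G, theta, alpha, r, th_num, th_den, a_num,
                            jmp, memb)
            if not np.isfinite(ll):
                raise FloatingPointError("non-finite HMM likelihood")
            if history and abs(ll - history[-1]) <= self.tol * abs(history[-1]):
                history.append(ll)
                break
            history.append(ll)
            # M-step
            with np.errstate(invalid="ignore", divide="ignore"):
                theta_new = th_num / th_den
            theta = np.where(np.isfinite(theta_new), theta_new, theta)
            theta = np.clip(theta, THETA_FLOOR, 1.0 - THETA_FLOOR)
            a = a_num + _ALPHA_PSEUDOCOUNT
            alpha = a / a.sum(axis=1, keepdims=True)
            if S > 1:
                r[1:] = jmp[1:] / (2.0 * N)
                r = np.clip(r, 0.0, 1.0 - 1e-12)
        # refresh memberships under the final parameters
        th_num = np.zeros((S, K))
        th_den = np.zeros((S, K))
        a_num = np.zeros((S, K))
        jmp = np.zeros(S)
        self.loglik_ = _hmm.estep(G, theta, alpha, r, th_num, th_den,
                                  a_num, jmp, memb)
        self.theta_, self.alpha_, self.rho_ = theta, alpha, r
        self.loglik_history_ = history
        self.memberships_ = memb
        self.positions_ = pos
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Expected per-cluster counts (N, S, K), each row summing to 2."""
        G = self._as_dosage(X)
        S, K = self.theta_.shape
        memb = np.empty((G.shape[0], S, K))
        _hmm.estep(G, self.theta_, self.alpha_, self.rho_,
                   np.zeros((S, K)), np.zeros((S, K)), np.zeros((S, K)),
                   np.zeros(S), memb)
        return memb

    def score(self, X, y=None) -> float:
        """Total log-likelihood of dosages X under the fitted model."""
        G = self._as_dosage(X)
        S, K = self.theta_.shape
        memb = np.empty((G.shape[0], S, K))
        return float(
            _hmm.estep(G, self.theta_, self.alpha_, self.rho_,
                       np.zeros((S, K)), np.zeros((S, K)),
                       np.zeros((S, K)), np.zeros(S), memb)
        )


def _pair_emission(g: int, theta_s: np.ndarray) -> np.ndarray:
    """P(genotype | ordered cluster pair) as a K x K matrix."""
    t = theta_s[:, None]
    u = theta_s[None, :]
    if g == 0:
        return (1 - t) * (1 - u)
    if g == 1:
        return t * (1 - u) + (1 - t) * u
    if g == 2:
        return t * u
    return np.ones((len(theta_s), len(theta_s)))


def genotype_forward_backward(dosages: np.ndarray, theta: np.ndarray,
                              alpha: np.ndarray, r: np.ndarray):
    """Posterior cluster-pair memberships for one individual's genotypes.

    The hidden state at SNP s is the (unordered) pair of clusters carried
    by the two chromosomes; the returned (S, K, K) array is the symmetric
    posterior over ordered pairs (summing to 1 at each SNP; fold the two
    off-diagonal triangles to obtain unordered-pair probabilities).  Also
    returns the log-likelihood.  Scaled probability space throughout.
    """
    g = np.asarray(dosages)
    if np.issubdtype(g.dtype, np.floating):
        g = np.where(np.isnan(g), MISSING, g)
    g = g.astype(int)
    S, K = theta.shape
    if g.shape != (S,):
        raise ValueError("dosages must be a 1-D array matching the model")
    F = np.empty((S, K, K))
    c = np.empty(S)
    for s in range(S):
        E = _pair_emission(g[s], theta[s])
        if s == 0:
            f = np.outer(alpha[0], alpha[0]) * E
        else:
            A = (1 - r[s]) * np.eye(K) + r[s] * np.ones((K, 1)) * alpha[s]
            f = (A.T @ F[s - 1] @ A) * E
        c[s] = f.sum()
        if not c[s] > 0:
            raise FloatingPointError("numerical underflow in forward pass")
        F[s] = f / c[s]
    post = np.empty((S, K, K))
    B = np.ones((K, K))
    for s in range(S - 1, -1, -1):
        gam = F[s] * B
        post[s] = gam / gam.sum()
        if s > 0:
            A = (1 - r[s]) * np.eye(K) + r[s] * np.ones((K, 1)) * alpha[s]
            C = _pair_emission(g[s], theta[s]) * B
            B = (A @ C @ A.T) / c[s]
    return post, float(np.log(c).sum())


def _genome_positions(g: GenotypeMatrix) -> np.ndarray:
    """Cumulative positions with a large gap at chromosome boundaries."""
    pos = g.pos.astype(np.int64).copy()
    offset = 0
    out = np.empty_like(pos)
    prev_chrom = None
    prev_end = 0
    for s in range(len(pos)):
        if g.chrom[s] != prev_chrom:
            if prev_chrom is not None:
                offset = prev_end + 10 * int(JUMP_SCALE_BP)
            prev_chrom = g.chrom[s]
            base = pos[s]
        out[s] = offset + (pos[s] - base)
        prev_end = out[s]
    return out


def cluster_frequencies(memberships: np.ndarray, populations: np.ndarray,
                        f0_populations: list) -> dict:
    """Per-population cluster frequencies at each SNP.

    memberships : (N, S, K) expected cluster counts; the frequency of
    cluster k in population j at SNP s is the population mean membership
    divided by 2 (two chromosomes per individual).  F1 individuals are
    excluded simply by omitting their label from ``f0_populations``.
    Each returned (S, K) row lies on the K-simplex.
    """
    populations = np.asarray(populations)
    out = {}
    for popl in f0_populations:
        m = populations == popl
        n = int(m.sum())
        if n == 0:
            raise ValueError(f"no individuals labelled {popl!r}")
        out[popl] = memberships[m].sum(axis=0) / (2.0 * n)
    return out
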