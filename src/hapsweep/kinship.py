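"""Population kinship from Reynolds distances and the single-SNP FLK test.

The FLK model treats per-population allele frequencies at a neutral SNP as
a draw around an ancestral frequency p0 with covariance p0(1-p0)F, where F
is the drift (kinship) matrix estimated from genome-wide Reynolds
distances.  Deviations standardized by this covariance give a chi-square
distributed differentiation statistic that separates selection from drift.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "KinshipMatrix",
    "reynolds_distance",
    "reynolds_matrix",
    "kinship_from_distances",
    "estimate_p0",
    "flk_statistic",
]


class UndefinedDistanceError(ValueError):
    """All SNPs identically fixed in both populations; distance undefined."""


@dataclass
class KinshipMatrix:
    """Expected drift covariance between populations.

    labels
        Ordered F0 population labels.
    F
        Symmetric PSD matrix; diagonal entries are root-to-leaf branch
        lengths, off-diagonals shared branch lengths.
    reynolds
        The pairwise Reynolds distance matrix F was derived from.
    """

    labels: list
    F: np.ndarray
    reynolds: np.ndarray

    @property
    def n_populations(self) -> int:
        return len(self.labels)


def reynolds_distance(p_i: np.ndarray, p_j: np.ndarray) -> float:
    """Reynolds coancestry distance between two allele-frequency vectors.

    D = sum_s (p_i - p_j)^2 / sum_s (1 - p_i p_j - (1-p_i)(1-p_j)),
    where the numerator is the half-sum of squared differences over the two
    alleles of each biallelic SNP.  Approximately linear in divergence time
    under pure drift.
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    if p_i.shape != p_j.shape:
        raise ValueError("frequency vectors must share the same SNP set")
    num = 0.5 * ((p_i - p_j) ** 2 + ((1 - p_i) - (1 - p_j)) ** 2).sum()
    den = (1.0 - p_i * p_j - (1 - p_i) * (1 - p_j)).sum()
    if den <= 0:
        raise UndefinedDistanceError(
            "Reynolds denominator is zero: all SNPs identically fixed"
        )
    return float(num / den)


def reynolds_matrix(freq: dict, labels: list) -> np.ndarray:
    """Pairwise Reynolds distances between populations (NaN SNPs dropped)."""
    J = len(labels)
    D = np.zeros((J, J))
    for a in range(J):
        for b in range(a + 1, J):
            pa, pb = np.asarray(freq[labels[a]]), np.asarray(freq[labels[b]])
            ok = np.isfinite(pa) & np.isfinite(pb)
            D[a, b] = D[b, a] = reynolds_distance(pa[ok], pb[ok])
    return D


def kinship_from_distances(reynolds: np.ndarray,
                           labels: list | None = None,
                           branch_split: float = 0.5) -> KinshipMatrix:
    """Build the drift matrix F from a Reynolds distance matrix.

    Two populations: midpoint rooting, F = diag(split*D, (1-split)*D) —
    there is no outgroup in a divergent-line design, so the symmetric
    midpoint (split 0.5) is the default.  More populations: neighbor
    joining with midpoint rooting; F_jj is the root-to-leaf branch sum and
    F_jk the shared root-to-MRCA branch length.  Negative NJ branch
    lengths are clamped to zero with a warning.
    """
    D = np.asarray(reynolds, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    J = D.shape[0]
    if labels is None:
        labels = [f"pop{i}" for i in range(J)]
    if J == 1:
        F = np.array([[0.0]])
    elif J == 2:
        d = D[0, 1]
        F = np.diag([branch_split * d, (1.0 - branch_split) * d])
    else:
        F = _kinship_nj(D, labels)
    return KinshipMatrix(labels=list(labels), F=F, reynolds=D)


def _kinship_nj(D: np.ndarray, labels: list) -> np.ndarray:
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(D, ids=[str(l) for l in labels]))
    n_neg = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_neg += 1
    if n_neg:
        warnings.warn(f"clamped {n_neg} negative NJ branch lengths to 0")
    tree = tree.root_at_midpoint()
    J = len(labels)
    F = np.zeros((J, J))
    tips = {t.name: t for t in tree.tips()}
    for a in range(J):
        ta = tips[str(labels[a])]
        F[a, a] = ta.accumulate_to_ancestor(tree)
        for b in range(a + 1, J):
            tb = tips[str(labels[b])]
            mrca = tree.lowest_common_ancestor([ta, tb])
            shared = mrca.accumulate_to_ancestor(tree) if mrca is not tree else 0.0
            F[a, b] = F[b, a] = shared
    return F


def estimate_p0(p: np.ndarray, kin: KinshipMatrix) -> float:
    """Ancestral allele frequency: GLS estimate (1'F^-1 p)/(1'F^-1 1).

    Falls back to the unweighted mean with a warning when F is singular.
    The result is clipped to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    ones = np.ones(len(p))
    try:
        w = np.linalg.solve(kin.F, ones)
        p0 = float(w @ p / (w @ ones))
    except np.linalg.LinAlgError:
        warnings.warn("singular kinship matrix; using unweighted mean for p0")
        p0 = float(p.mean())
    return float(np.clip(p0, 0.0, 1.0))


def flk_statistic(p: np.ndarray, kin: KinshipMatrix) -> float:
    """Single-SNP FLK: drift-standardized allele-frequency differentiation.

    T = (p - p0 1)' [p0 (1-p0) F]^{-1} (p - p0 1).  Under neutrality T is
    approximately chi-square with J-1 degrees of freedom.  Returns NaN
    (non-informative) when the estimated p0 is at a boundary.
    """
    p = np.asarray(p, dtype=float)
    p0 = estimate_p0(p, kin)
    if p0 <= 0.0 or p0 >= 1.0:
        return float("nan")
    d = p - p0
    cov = p0 * (1.0 - p0) * kin.F
    return float(d @ np.linalg.solve(cov, d))
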