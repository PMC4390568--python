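"""Numba kernels for the haplotype-cluster genotype HMM.

A chromosome is modeled as a mosaic of K latent clusters: the cluster path
switches ("jumps") between SNPs with probability r_s and, on a jump,
redraws from the local cluster weights alpha[s].  Alleles are emitted
Bernoulli(theta[s, k]).  An unphased genotype is the sum of two
independent paths, so the hidden state at a SNP is an (ordered) cluster
pair and all matrices below are K x K.  Forward-backward is run in scaled
probability space; every buffer is allocated once per call.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MISSING = -1


@njit(cache=True)
def _emission(E, theta_s, g):
    K = theta_s.shape[0]
    for k in range(K):
        tk = theta_s[k]
        for l in range(K):
            tl = theta_s[l]
            if g == 0:
                E[k, l] = (1.0 - tk) * (1.0 - tl)
            elif g == 1:
                E[k, l] = tk * (1.0 - tl) + (1.0 - tk) * tl
            elif g == 2:
                E[k, l] = tk * tl
            else:
                E[k, l] = 1.0


@njit(cache=True)
def estep(G, theta, alpha, r, th_num, th_den, a_num, jmp_num, memb):
    """One accumulation E-step over all individuals.

    G : (N, S) int8 dosages (-1 missing); theta, alpha : (S, K); r : (S,)
    with r[0] unused.  Accumulators th_num/th_den (expected alt counts and
    cluster occupancies, informative SNPs only), a_num (expected draws
    from alpha: initial states at s=0, jump destinations at s>0), jmp_num
    (expected jumps per interval) are +='d in place; memb (N, S, K) is
    overwritten with expected cluster counts in [0, 2].  Returns the total
    log-likelihood under the *current* parameters.
    """
    N, S = G.shape
    K = theta.shape[1]
    F = np.empty((S, K, K))
    c = np.empty(S)
    E = np.empty((K, K))
    B = np.empty((K, K))
    Bn = np.empty((K, K))
    T1 = np.empty((K, K))
    Gm = np.empty((K, K))
    FA = np.empty((K, K))
    M = np.empty((K, K))
    AC = np.empty((K, K))
    total_ll = 0.0

    for i in range(N):
        # ---- forward ----
        for s in range(S):
            _emission(E, theta[s], G[i, s])
            if s == 0:
                for k in range(K):
                    for l in range(K):
                        F[0, k, l] = alpha[0, k] * alpha[0, l] * E[k, l]
            else:
                rs = r[s]
                # T1 = A^T F_{s-1}
                for l in range(K):
                    col = 0.0
                    for k in range(K):
                        col += F[s - 1, k, l]
                    for kp in range(K):
                        T1[kp, l] = (1.0 - rs) * F[s - 1, kp, l] \
                            + rs * alpha[s, kp] * col
                # F_s = (T1 A) o E
                for kp in range(K):
                    row = 0.0
                    for l in range(K):
                        row += T1[kp, l]
                    for lp in range(K):
                        F[s, kp, lp] = ((1.0 - rs) * T1[kp, lp]
                                        + rs * alpha[s, lp] * row) * E[kp, lp]
            z = 0.0
            for k in range(K):
                for l in range(K):
                    z += F[s, k, l]
            c[s] = z
            inv = 1.0 / z
            for k in range(K):
                for l in range(K):
                    F[s, k, l] *= inv
            total_ll += np.log(z)

        # ---- backward with accumulation ----
        for k in range(K):
            for l in range(K):
                B[k, l] = 1.0
        for s in range(S - 1, -1, -1):
            g = G[i, s]
            gsum = 0.0
            for k in range(K):
                for l in range(K):
                    Gm[k, l] = F[s, k, l] * B[k, l]
                    gsum += Gm[k, l]
            inv = 1.0 / gsum
            for k in range(K):
                mk = 0.0
                ak = 0.0
                for l in range(K):
                    gam = Gm[k, l] * inv
                    mk += gam
                    if g == 1:
                        tk = theta[s, k]
                        tl = theta[s, l]
                        den = tk * (1.0 - tl) + (1.0 - tk) * tl
                        if den > 0.0:
                            ak += gam * tk * (1.0 - tl) / den
                        else:
                            ak += gam * 0.5
                    elif g == 2:
                        ak += gam
                memb[i, s, k] = 2.0 * mk
                if g >= 0:
                    th_num[s, k] += 2.0 * ak
                    th_den[s, k] += 2.0 * mk
                if s == 0:
                    a_num[0, k] += 2.0 * mk
            if s == 0:
                break

            # jump statistics for the s-1 -> s transition (per chromosome,
            # doubled for the two chromosomes by symmetry)
            rs = r[s]
            _emission(E, theta[s], g)
            # C = E o B  (reuse E in place)
            for k in range(K):
                for l in range(K):
                    E[k, l] *= B[k, l]
            # FA = F_{s-1} A
            for k in range(K):
                row = 0.0
                for l in range(K):
                    row += F[s - 1, k, l]
                for lp in range(K):
                    FA[k, lp] = (1.0 - rs) * F[s - 1, k, lp] \
                        + rs * alpha[s, lp] * row
            # M = FA C^T ; Z = sum A o M
            Z = 0.0
            for k in range(K):
                for kp in range(K):
                    acc = 0.0
                    for lp in range(K):
                        acc += FA[k, lp] * E[kp, lp]
                    M[k, kp] = acc
                    a_kkp = rs * alpha[s, kp]
                    if k == kp:
                        a_kkp += 1.0 - rs
                    Z += a_kkp * acc
            invZ = 1.0 / Z
            jtot = 0.0
            for kp in range(K):
                u = 0.0
                for k in range(K):
                    u += M[k, kp]
                jm = rs * alpha[s, kp] * u * invZ
                a_num[s, kp] += 2.0 * jm
                jtot += jm
            jmp_num[s] += 2.0 * jtot

            # B_{s-1} = A C A^T / c_s   (C currently stored in E)
            for lp in range(K):
                colmix = 0.0
                for kp in range(K):
                    colmix += alpha[s, kp] * E[kp, lp]
                for k in range(K):
                    AC[k, lp] = (1.0 - rs) * E[k, lp] + rs * colmix
            invc = 1.0 / c[s]
            for k in range(K):
                rowmix = 0.0
                for lp in range(K):
                    rowmix += alpha[s, lp] * AC[k, lp]
                for l in range(K):
                    Bn[k, l] = ((1.0 - rs) * AC[k, l] + rs * rowmix) * invc
            for k in range(K):
                for l in range(K):
                    B[k, l] = Bn[k, l]
    return total_ll
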