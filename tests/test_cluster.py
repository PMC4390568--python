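import itertools

import numpy as np
import pytest

from hapsweep.cluster import (ClusterConfig, HaplotypeClusterModel,
                              cluster_frequencies, genotype_forward_backward,
                              init_params)


def brute_force_posteriors(g, theta, alpha, r):
    """Posterior over ordered cluster pairs by full path enumeration."""
    S, K = theta.shape

    def path_prob(path):
        p = alpha[0, path[0]]
        for s in range(1, S):
            p *= (1 - r[s]) * (path[s] == path[s - 1]) + r[s] * alpha[s, path[s]]
        return p

    def emit(gs, k, l, s):
        tk, tl = theta[s, k], theta[s, l]
        if gs == 0:
            return (1 - tk) * (1 - tl)
        if gs == 1:
            return tk * (1 - tl) + (1 - tk) * tl
        if gs == 2:
            return tk * tl
        return 1.0

    post = np.zeros((S, K, K))
    total = 0.0
    for p1 in itertools.product(range(K), repeat=S):
        pp1 = path_prob(p1)
        for p2 in itertools.product(range(K), repeat=S):
            w = pp1 * path_prob(p2)
            for s in range(S):
                w *= emit(g[s], p1[s], p2[s], s)
            total += w
            for s in range(S):
                post[s, p1[s], p2[s]] += w
    return post / total, np.log(total)


def random_instance(rng, S, K, with_missing=False):
    theta = rng.uniform(0.1, 0.9, (S, K))
    alpha = rng.dirichlet(np.ones(K), size=S)
    r = np.concatenate([[0.0], rng.uniform(0.0, 1.0, S - 1)])
    g = rng.integers(0, 3, size=S)
    if with_missing:
        g[rng.integers(S)] = -1
    return g, theta, alpha, r


def simulate_from_model(rng, S, N, K, theta, jump=0.05):
    haps = np.zeros((2 * N, S), dtype=int)
    z = rng.integers(K, size=2 * N)
    for s in range(S):
        move = rng.random(2 * N) < jump
        z = np.where(move, rng.integers(K, size=2 * N), z)
        haps[:, s] = rng.random(2 * N) < theta[s, z]
    return haps[0::2] + haps[1::2]


class TestInitParams:
    def test_deterministic_for_seed_and_fit_index(self):
        cfg = ClusterConfig(K=4, seed=9)
        pos = np.arange(10) * 500
        a = init_params(cfg, pos, fit_index=3)
        b = init_params(cfg, pos, fit_index=3)
        c = init_params(cfg, pos, fit_index=4)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        assert not np.allclose(a[0], c[0])

    def test_k1_alpha_uniform(self):
        theta, alpha, r = init_params(ClusterConfig(K=1), np.arange(5) * 1000, 0)
        assert np.all(alpha == 1.0)

    def test_colocated_snps_no_jump(self):
        pos = np.array([100, 100, 50100])
        _, _, r = init_params(ClusterConfig(K=2), pos, 0)
        assert r[1] == 0.0
        assert r[2] == pytest.approx(1 - np.exp(-1.0))


class TestForwardBackward:
    @pytest.mark.parametrize("S,K,missing", [(3, 2, False), (4, 3, False),
                                             (4, 2, True), (2, 3, False)])
    def test_matches_path_enumeration(self, rng, S, K, missing):
        g, theta, alpha, r = random_instance(rng, S, K, with_missing=missing)
        post, ll = genotype_forward_backward(g, theta, alpha, r)
        bpost, bll = brute_force_posteriors(g, theta, alpha, r)
        assert ll == pytest.approx(bll, rel=1e-10)
        np.testing.assert_allclose(post, bpost, atol=1e-10)
        np.testing.assert_allclose(post.sum(axis=(1, 2)), 1.0)

    def test_k1_closed_form(self, rng):
        S = 6
        theta = rng.uniform(0.2, 0.8, (S, 1))
        alpha = np.ones((S, 1))
        r = np.concatenate([[0], rng.uniform(0, 1, S - 1)])
        g = rng.integers(0, 3, S)
        post, ll = genotype_forward_backward(g, theta, alpha, r)
        t = theta[:, 0]
        per_snp = np.where(g == 0, (1 - t) ** 2,
                           np.where(g == 1, 2 * t * (1 - t), t ** 2))
        assert ll == pytest.approx(np.log(per_snp).sum(), rel=1e-12)
        np.testing.assert_allclose(post, 1.0)

    def test_no_jumps_factorizes_as_global_mixture(self, rng):
        # r = 0 everywhere: the pair is constant, so posteriors equal the
        # global mixture over K(K+1)/2 assignments
        S, K = 3, 2
        theta = rng.uniform(0.2, 0.8, (S, K))
        alpha0 = rng.dirichlet(np.ones(K))
        alpha = np.tile(alpha0, (S, 1))
        r = np.zeros(S)
        g = rng.integers(0, 3, S)
        post, _ = genotype_forward_backward(g, theta, alpha, r)

        def emitprod(k, l):
            out = alpha0[k] * alpha0[l]
            for s in range(S):
                tk, tl = theta[s, k], theta[s, l]
                e = [(1 - tk) * (1 - tl), tk * (1 - tl) + (1 - tk) * tl,
                     tk * tl][g[s]]
                out *= e
            return out

        w = np.array([[emitprod(k, l) for l in range(K)] for k in range(K)])
        w /= w.sum()
        for s in range(S):
            np.testing.assert_allclose(post[s], w, atol=1e-12)


class TestEMFit:
    def test_loglik_monotone_and_memberships_normalized(self, rng):
        G = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        m = HaplotypeClusterModel(n_clusters=3, n_iter=15,
                                  random_state=0).fit(G)
        ll = np.array(m.loglik_history_)
        assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))
        np.testing.assert_allclose(m.memberships_.sum(axis=2), 2.0,
                                   atol=1e-9)
        np.testing.assert_allclose(m.alpha_.sum(axis=1), 1.0, atol=1e-12)

    def test_parameter_recovery_two_clusters(self, rng):
        S, N, K = 50, 40, 2
        theta = rng.uniform(0.05, 0.95, (S, K))
        G = simulate_from_model(rng, S, N, K, theta)
        fits = [HaplotypeClusterModel(n_clusters=K, n_iter=30,
                                      random_state=1, fit_index=i).fit(
                    G, positions=np.arange(S) * 1000) for i in range(5)]
        m = max(fits, key=lambda f: f.loglik_)
        best = max(
            np.corrcoef(m.theta_[:, list(p)].ravel(), theta.ravel())[0, 1]
            for p in itertools.permutations(range(K)))
        assert best > 0.9

    def test_k1_theta_equals_observed_frequency(self, rng):
        G = rng.integers(0, 3, size=(20, 15)).astype(np.int8)
        m = HaplotypeClusterModel(n_clusters=1, n_iter=10,
                                  random_state=0).fit(G)
        freq = np.clip(G.mean(axis=0) / 2, 1e-3, 1 - 1e-3)
        np.testing.assert_allclose(m.theta_[:, 0], freq, atol=1e-8)

    def test_empty_or_single_individual_rejected(self):
        with pytest.raises(ValueError):
            HaplotypeClusterModel().fit(np.zeros((1, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            HaplotypeClusterModel().fit(np.zeros((3, 0), dtype=np.int8))

    def test_missing_dosages_handled(self, rng):
        G = rng.integers(0, 3, size=(8, 20)).astype(np.int8)
        G[rng.random(G.shape) < 0.2] = -1
        m = HaplotypeClusterModel(n_clusters=2, n_iter=10,
                                  random_state=2).fit(G)
        assert np.isfinite(m.loglik_)


class TestClusterFrequencies:
    def test_single_individual_fully_assigned(self):
        memb = np.zeros((1, 3, 2))
        memb[0, :, 0] = 2.0
        out = cluster_frequencies(memb, np.array(["lineA"]), ["lineA"])
        np.testing.assert_allclose(out["lineA"], [[1, 0]] * 3)

    def test_two_individuals_split(self):
        memb = np.zeros((2, 1, 2))
        memb[0, 0] = [2, 0]
        memb[1, 0] = [0, 2]
        out = cluster_frequencies(memb, np.array(["lineA", "lineA"]),
                                  ["lineA"])
        np.testing.assert_allclose(out["lineA"], [[0.5, 0.5]])

    def test_matches_hand_average_and_simplex(self, rng):
        N, S, K = 6, 4, 3
        raw = rng.dirichlet(np.ones(K), size=(N, S)) * 2
        pops = np.array(["lineA"] * 3 + ["lineB"] * 2 + ["F1"])
        out = cluster_frequencies(raw, pops, ["lineA", "lineB"])
        np.testing.assert_allclose(out["lineA"],
                                   raw[:3].sum(axis=0) / 6.0)
        np.testing.assert_allclose(out["lineB"].sum(axis=1), 1.0)
        assert "F1" not in out
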