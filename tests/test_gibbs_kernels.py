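"""Gibbs kernels against closed forms, quadrature, and exhaustive enumeration."""

import itertools

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from hmmbiclust import (ExpressionMatrix, Hyperparams, LatentState,
                        complete_loglik, sufficient_stats)
from hmmbiclust.gibbs import (_ig_draw, _mu_cluster_posterior,
                              _mu_feature_posterior, _truncnorm_draw,
                              rho_site_conditional, update_mu_cluster,
                              update_mu_feature, update_omega,
                              update_rho_column, update_sigma2_cluster,
                              update_sigma2_feature, update_sigma2_irrelevant,
                              update_xi, update_z, z_conditional)

from .conftest import make_params, make_state


class TestOmegaUpdate:
    def test_posterior_moments(self):
        # z = (1, 1, 2) with alpha = (1, 1): posterior Dirichlet(3, 2)
        hp = Hyperparams(K=2)
        rng = np.random.default_rng(0)
        draws = np.array([update_omega(np.array([1, 1, 2]), hp, rng)
                          for _ in range(20000)])
        mean = draws.mean(axis=0)
        sd = np.sqrt(3 * 2 / (25 * 6))
        se = sd / np.sqrt(len(draws))
        assert abs(mean[0] - 0.6) < 4 * se
        assert abs(mean[1] - 0.4) < 4 * se

    def test_no_data_reduces_to_prior(self):
        hp = Hyperparams(K=2)
        rng = np.random.default_rng(1)
        draws = np.array([update_omega(np.array([], dtype=int), hp, rng)
                          for _ in range(20000)])
        se = np.sqrt(0.25 / 3) / np.sqrt(len(draws))
        assert abs(draws[:, 0].mean() - 0.5) < 4 * se


class TestXiUpdate:
    def test_counts_from_hand_example(self):
        # K=1, p=4, chain (1,1,2,3): row 1 posterior Dirichlet(2, 2, 1)
        hp = Hyperparams(K=1)
        rng = np.random.default_rng(2)
        rho = np.array([[1], [1], [2], [3]])
        draws = np.array([update_xi(rho, hp, rng)[0] for _ in range(20000)])
        target = np.array([2, 2, 1]) / 5
        var = target * (1 - target) / 6
        se = np.sqrt(var / len(draws))
        assert (np.abs(draws.mean(axis=0) - target) < 4 * se).all()

    def test_constant_state_three(self):
        # all chains in state 3: row 3 sees K(p-1) self-transitions
        hp = Hyperparams(K=2)
        rng = np.random.default_rng(3)
        rho = np.full((5, 2), 3)
        draws = np.array([update_xi(rho, hp, rng)[2, 2] for _ in range(5000)])
        target = 9 / 11   # Dir(1, 1, 1 + 8) third component mean
        se = np.sqrt(target * (1 - target) / 12) / np.sqrt(len(draws))
        assert abs(draws.mean() - target) < 4 * se


def _truncnorm_mean_quadrature(t, loc, sd):
    """Independent oracle: mean of N(loc, sd^2) truncated to (t, inf)."""
    Z, _ = integrate.quad(lambda x: norm.pdf(x, loc, sd), t, np.inf)
    m, _ = integrate.quad(lambda x: x * norm.pdf(x, loc, sd), t, np.inf)
    return m / Z


class TestMuClusterUpdate:
    def test_empty_state_reduces_to_prior(self, rng):
        hp = Hyperparams(K=1, sigma2_mu0=4.0)
        params = make_params(2, 1, rng)
        stats = sufficient_stats(ExpressionMatrix(rng.normal(size=(2, 2))),
                                 LatentState([1, 1], np.full((2, 1), 3)), params)
        draws = np.array([update_mu_cluster(0, 1, stats, params, hp, rng)
                          for _ in range(4000)])
        target = _truncnorm_mean_quadrature(hp.t, hp.mu0, 2.0)
        assert abs(draws.mean() - target) < 4 * draws.std() / np.sqrt(len(draws))

    def test_constraint_sign_and_support(self, rng):
        hp = Hyperparams(K=1)
        params = make_params(4, 1, rng)
        state = make_state(6, 4, 1, rng)
        Y = ExpressionMatrix(rng.normal(size=(6, 4)))
        stats = sufficient_stats(Y, state, params)
        for _ in range(200):
            assert update_mu_cluster(0, 1, stats, params, hp, rng) > hp.t
            assert update_mu_cluster(0, 2, stats, params, hp, rng) < -hp.t

    def test_truncated_posterior_mean_vs_quadrature(self):
        # informative case: M=12.0 over N=10 features, sigma2_kl=2
        hp = Hyperparams(K=1, sigma2_mu0=1000.0)
        loc, var = _mu_cluster_posterior(12.0, 10, 2.0, hp)
        rng = np.random.default_rng(7)
        draws = _truncnorm_draw(rng, hp.t, np.full(100000, loc), np.sqrt(var))
        target = _truncnorm_mean_quadrature(hp.t, loc, np.sqrt(var))
        assert abs(draws.mean() - target) < 4 * draws.std() / np.sqrt(draws.size)

    def test_underexpressed_sign_flip_of_location(self, rng):
        # for l=2 the magnitude posterior uses -M: strongly negative feature
        # means must give a strongly negative mu_k2, not one stuck at -t
        hp = Hyperparams(K=1)
        params = make_params(30, 1, rng)
        rho = np.full((30, 1), 2)
        state = LatentState([1], rho)
        params.mu_feature[:, 0, 1] = -3.0
        stats = sufficient_stats(ExpressionMatrix(rng.normal(size=(1, 30))),
                                 state, params)
        draws = np.array([update_mu_cluster(0, 2, stats, params, hp, rng)
                          for _ in range(500)])
        assert draws.mean() < -2.0

    def test_unconstrained_matches_conjugate_normal(self, rng):
        hp = Hyperparams(K=1, variant_constraint=False)
        params = make_params(5, 1, rng)
        state = make_state(4, 5, 1, rng)
        stats = sufficient_stats(ExpressionMatrix(rng.normal(size=(4, 5))),
                                 state, params)
        loc, var = _mu_cluster_posterior(stats.M_kl[0, 0], stats.N_kl[0, 0],
                                         params.sigma2_cluster[0, 0], hp)
        draws = np.array([update_mu_cluster(0, 1, stats, params, hp, rng)
                          for _ in range(20000)])
        assert abs(draws.mean() - loc) < 4 * np.sqrt(var / len(draws))
        assert abs(draws.var() - var) < 4 * var * np.sqrt(2 / len(draws))


class TestVarianceUpdates:
    def test_empty_state_is_prior(self, rng):
        # IG(1, 1) prior: median 1/log(2)
        hp = Hyperparams(K=1)
        params = make_params(2, 1, rng)
        stats = sufficient_stats(ExpressionMatrix(rng.normal(size=(2, 2))),
                                 LatentState([1, 1], np.full((2, 1), 3)), params)
        draws = np.array([update_sigma2_cluster(0, 1, stats, hp, rng)
                          for _ in range(20000)])
        med = np.median(draws)
        assert abs(med - 1 / np.log(2)) < 0.1

    def test_inverse_gamma_moments(self):
        # vectorized draw with shape 4, scale 6: mean 2, var 4/2 = 2
        rng = np.random.default_rng(11)
        draws = _ig_draw(rng, np.full(100000, 4.0), 6.0)
        mean, var = 2.0, 2.0
        assert abs(draws.mean() - mean) < 4 * np.sqrt(var / draws.size)

    def test_sigma2_cluster_concentrates(self, rng):
        # many features in state 1 with fixed spread: posterior near S2/N
        hp = Hyperparams(K=1)
        p = 2000
        params = make_params(p, 1, rng)
        params.mu_cluster[0, 0] = 1.0
        params.mu_feature[:, 0, 0] = 1.0 + 0.5 * rng.standard_normal(p)
        state = LatentState([1], np.full((p, 1), 1))
        stats = sufficient_stats(ExpressionMatrix(rng.normal(size=(1, p))),
                                 state, params)
        draws = np.array([update_sigma2_cluster(0, 1, stats, hp, rng)
                          for _ in range(200)])
        assert abs(draws.mean() - 0.25) < 0.05

    def test_irrelevant_variance_scoping_matches_loop(self, rng):
        # the (N, S2) entering the draw must match a nested loop over the
        # samples whose cluster marks feature j irrelevant
        n, p, K = 6, 5, 2
        Y = ExpressionMatrix(rng.normal(size=(n, p)))
        state = make_state(n, p, K, rng)
        hp = Hyperparams(K=K)
        for j in range(p):
            N = S2 = 0.0
            for i in range(n):
                if state.rho[j, state.z[i] - 1] == 3:
                    N += 1
                    S2 += Y.values[i, j] ** 2
            d1 = update_sigma2_irrelevant(j, Y, state, hp,
                                          np.random.default_rng(99))
            d2 = float(_ig_draw(np.random.default_rng(99),
                                hp.a0 + N / 2, hp.b0 + S2 / 2))
            assert d1 == pytest.approx(d2, rel=1e-12)

    def test_feature_variance_scoping_matches_loop(self, rng):
        n, p, K = 6, 5, 2
        Y = ExpressionMatrix(rng.normal(size=(n, p)))
        state = make_state(n, p, K, rng)
        params = make_params(p, K, rng)
        hp = Hyperparams(K=K)
        for j, k, l in itertools.product(range(p), range(K), (1, 2)):
            N = S2 = 0.0
            for i in range(n):
                if state.rho[j, k] == l and state.z[i] == k + 1:
                    N += 1
                    S2 += (Y.values[i, j] - params.mu_feature[j, k, l - 1]) ** 2
            d1 = update_sigma2_feature(j, k, l, Y, state, params, hp,
                                       np.random.default_rng(5))
            d2 = float(_ig_draw(np.random.default_rng(5),
                                hp.a0 + N / 2, hp.b0 + S2 / 2))
            assert d1 == pytest.approx(d2, rel=1e-12)


class TestMuFeatureUpdate:
    def test_empty_cluster_draws_from_cluster_prior(self, rng):
        n, p, K = 4, 3, 2
        Y = ExpressionMatrix(rng.normal(size=(n, p)))
        state = make_state(n, p, K, rng)
        state.z[:] = 1  # cluster 2 empty
        params = make_params(p, K, rng)
        hp = Hyperparams(K=K)
        draws = np.array([update_mu_feature(0, 1, 1, Y, state, params, hp, rng)
                          for _ in range(20000)])
        mu, s2 = params.mu_cluster[1, 0], params.sigma2_cluster[1, 0]
        assert abs(draws.mean() - mu) < 4 * np.sqrt(s2 / len(draws))

    def test_flat_prior_limit_gives_sample_mean(self, rng):
        mean, var = _mu_feature_posterior(5.0, 1e12, 1.0, Mp=30.0, Np=10)
        assert mean == pytest.approx(3.0, rel=1e-6)
        assert var == pytest.approx(0.1, rel=1e-6)

    def test_posterior_matches_precision_weighted_form(self, rng):
        n, p, K = 5, 4, 1
        Y = ExpressionMatrix(rng.normal(size=(n, p)))
        state = LatentState(np.ones(n, dtype=int), np.full((p, K), 1))
        params = make_params(p, K, rng)
        hp = Hyperparams(K=K)
        j = 2
        Mp = Y.values[:, j].sum()
        mu_kl, s2_kl = params.mu_cluster[0, 0], params.sigma2_cluster[0, 0]
        s2_jkl = params.sigma2_feature[j, 0, 0]
        mean = (mu_kl * s2_jkl / s2_kl + Mp) / (s2_jkl / s2_kl + n)
        var = 1 / (1 / s2_kl + n / s2_jkl)
        d1 = update_mu_feature(j, 0, 1, Y, state, params, hp,
                               np.random.default_rng(123))
        d2 = float(np.random.default_rng(123).normal(mean, np.sqrt(var)))
        assert d1 == pytest.approx(d2, rel=1e-12)


def _enumerate_joint(Y, z, params, hp):
    """Exact joint over all 3^(p*K) state chains given fixed z and params."""
    p, K = params.p, params.K
    configs, weights = [], []
    for states in itertools.product((1, 2, 3), repeat=p * K):
        rho = np.array(states).reshape(p, K)
        st = LatentState(z, rho)
        configs.append(rho)
        weights.append(np.exp(complete_loglik(Y, st, params, hp)))
    weights = np.array(weights)
    return configs, weights / weights.sum()


class TestRhoConditionals:
    def test_site_conditionals_match_enumeration(self, tiny_problem):
        # n=2, p=3, K=1: every site's conditional from the kernel equals the
        # exact conditional from enumerating all 27 chains of the joint
        Y, params, hp = tiny_problem
        z = np.array([1, 1])
        configs, probs = _enumerate_joint(Y, z, params, hp)
        for base, _ in zip(configs, probs):
            state = LatentState(z, base.copy())
            for j in range(3):
                num = np.zeros(3)
                for l in (1, 2, 3):
                    rho = base.copy()
                    rho[j, 0] = l
                    for cfg, pr in zip(configs, probs):
                        if (cfg == rho).all():
                            num[l - 1] = pr
                exact = num / num.sum()
                kernel = rho_site_conditional(j, 0, Y, state, params, hp)
                np.testing.assert_allclose(kernel, exact, atol=1e-10)

    def test_empty_cluster_reduces_to_chain_prior(self, rng):
        # interior site of a memberless cluster: P(l) prop xi[left, l] xi[l, right]
        p, K = 3, 2
        Y = ExpressionMatrix(rng.normal(size=(2, p)))
        params = make_params(p, K, rng)
        state = LatentState(np.array([1, 1]), 1 + rng.integers(0, 3, (p, K)))
        hp = Hyperparams(K=K)
        left, right = state.rho[0, 1] - 1, state.rho[2, 1] - 1
        expected = params.xi[left, :] * params.xi[:, right]
        expected = expected / expected.sum()
        np.testing.assert_allclose(
            rho_site_conditional(1, 1, Y, state, params, hp), expected,
            atol=1e-12)

    def test_scan_recovers_truth_on_separated_data(self, rng):
        # |y - mu| huge for wrong states: the scan must return the truth
        p = 20
        truth = np.array([1] * 7 + [2] * 7 + [3] * 6)
        mu = np.where(truth == 1, 50.0, np.where(truth == 2, -50.0, 0.0))
        Y = ExpressionMatrix(mu[None, :] + 0.01 * rng.standard_normal((5, p)))
        params = make_params(p, 1, rng)
        params.mu_feature[:, 0, 0] = 50.0
        params.mu_feature[:, 0, 1] = -50.0
        params.sigma2_feature[:] = 1.0
        params.sigma2_irrelevant[:] = 1.0
        params.xi = np.full((3, 3), 1 / 3)
        state = LatentState(np.ones(5, dtype=int), np.full((p, 1), 3))
        hp = Hyperparams(K=1)
        new = update_rho_column(0, Y, state, params, hp, rng)
        np.testing.assert_array_equal(new, truth)


class TestZUpdate:
    def test_single_cluster(self, rng):
        Y = ExpressionMatrix(rng.normal(size=(4, 3)))
        state = make_state(4, 3, 1, rng)
        params = make_params(3, 1, rng)
        assert (update_z(Y, state, params, Hyperparams(K=1), rng) == 1).all()

    def test_symmetric_clusters_are_uniform(self, rng):
        # identical parameters and omega = 1/2: conditional exactly uniform
        p, K = 3, 2
        Y = ExpressionMatrix(rng.normal(size=(2, p)))
        params = make_params(p, K, rng)
        params.omega = np.array([0.5, 0.5])
        for f in ("mu_cluster", "sigma2_cluster"):
            getattr(params, f)[1] = getattr(params, f)[0]
        params.mu_feature[:, 1, :] = params.mu_feature[:, 0, :]
        params.sigma2_feature[:, 1, :] = params.sigma2_feature[:, 0, :]
        rho = 1 + np.random.default_rng(0).integers(0, 3, (p, 1))
        state = LatentState(np.array([1, 2]), np.repeat(rho, K, axis=1))
        np.testing.assert_allclose(z_conditional(0, Y, state, params),
                                   [0.5, 0.5], atol=1e-12)

    def test_conditional_matches_hand_evaluation(self, rng):
        # p=2, K=2: direct evaluation of the label conditional
        p, K = 2, 2
        Y = ExpressionMatrix(rng.normal(size=(1, p)))
        params = make_params(p, K, rng)
        state = make_state(1, p, K, rng)
        logw = np.zeros(K)
        for k in range(K):
            logw[k] = np.log(params.omega[k])
            for j in range(p):
                l = state.rho[j, k]
                if l == 3:
                    mu, s2 = 0.0, params.sigma2_irrelevant[j]
                else:
                    mu = params.mu_feature[j, k, l - 1]
                    s2 = params.sigma2_feature[j, k, l - 1]
                logw[k] += norm.logpdf(Y.values[0, j], mu, np.sqrt(s2))
        expected = np.exp(logw - logw.max())
        expected /= expected.sum()
        np.testing.assert_allclose(z_conditional(0, Y, state, params),
                                   expected, atol=1e-12)

    def test_z_conditional_matches_joint_enumeration(self, tiny_problem):
        # conditional of z_1 from the kernel equals the normalized joint of
        # the two completions, with rho and everything else held fixed
        Y, params, hp = tiny_problem
        K = 2
        rng = np.random.default_rng(8)
        params2 = make_params(3, K, rng)
        state = make_state(2, 3, K, rng)
        w = np.zeros(K)
        for k in range(K):
            z = state.z.copy()
            z[0] = k + 1
            w[k] = np.exp(complete_loglik(Y, LatentState(z, state.rho),
                                          params2, hp.__class__(K=K)))
        np.testing.assert_allclose(z_conditional(0, Y, state, params2),
                                   w / w.sum(), atol=1e-10)
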