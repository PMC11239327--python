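"""Gibbs sampler: conjugate full-conditional kernels and the MCMC loop.

One iteration updates, in order: the cluster probabilities Omega; the
per-feature means mu_jkl and the cluster-level means mu_kl; all variances
(sigma2_kl, sigma2_jkl, sigma2_j3); the transition matrix xi; the cluster
labels z; and finally the feature-state chains rho (single-site systematic
scan per cluster).

Four model variants are supported through :class:`~hmmbiclust.core.Hyperparams`:

* ``variant_hmm`` — Markov prior on the feature states along the ordered axis
  (otherwise i.i.d. uniform categorical states, and xi is not updated);
* ``variant_constraint`` — truncation of the cluster means (mu_k1 > t,
  mu_k2 < -t; otherwise untruncated normals, leaving the two relevant state
  labels unidentifiable — see ``align_variant_labels``).

Scalar kernels (``update_*``) expose the exact per-coordinate conditionals
for testing; the run loop uses vectorized twins built on the same posterior
formulas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.special import gammaln
from scipy.stats import truncnorm

from ._scan import scan_chain
from .core import (LOG_2PI, ExpressionMatrix, Hyperparams, LatentState,
                   ModelParams, SufficientStats, _assigned_mean_var, _safe_log,
                   complete_loglik, observed_loglik)

__all__ = [
    "MCMCTrace", "run_gibbs",
    "update_omega", "update_xi", "update_mu_cluster", "update_sigma2_cluster",
    "update_sigma2_irrelevant", "update_sigma2_feature", "update_mu_feature",
    "update_rho_column", "update_z",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# posterior-parameter helpers (shared by scalar kernels and vectorized loop)

def _mu_cluster_posterior(M, N, sigma2_kl, hp: Hyperparams):
    """Location/variance of the mu_kl conditional given the signed stat M."""
    c = sigma2_kl / hp.sigma2_mu0
    loc = (hp.mu0 * c + M) / (c + N)
    var = 1.0 / (1.0 / hp.sigma2_mu0 + N / sigma2_kl)
    return loc, var


def _mu_feature_posterior(mu_kl, sigma2_kl, sigma2_jkl, Mp, Np):
    w = sigma2_jkl / sigma2_kl
    mean = (mu_kl * w + Mp) / (w + Np)
    var = 1.0 / (1.0 / sigma2_kl + Np / sigma2_jkl)
    return mean, var


def _ig_draw(rng: np.random.Generator, shape, scale):
    """Inverse-gamma draw(s): scale / Gamma(shape, 1)."""
    return np.asarray(scale) / rng.gamma(shape)


def _truncnorm_draw(rng: np.random.Generator, t, loc, scale):
    a = (np.asarray(t) - loc) / scale
    return truncnorm.rvs(a, np.inf, loc=loc, scale=scale, random_state=rng)


# ---------------------------------------------------------------------------
# scalar kernels (the printed full conditionals, one coordinate at a time)

def update_omega(z: np.ndarray, hp: Hyperparams,
                 rng: np.random.Generator) -> np.ndarray:
    """Dirichlet(alpha_k + cluster counts) draw of the cluster probabilities."""
    counts = np.bincount(np.asarray(z, int) - 1, minlength=hp.K)
    return rng.dirichlet(hp.alpha + counts)


def transition_counts(rho: np.ndarray) -> np.ndarray:
    """3x3 state-transition counts pooled over the K feature chains."""
    rho = np.asarray(rho, int)
    n_rl = np.zeros((3, 3), dtype=int)
    if rho.shape[0] > 1:
        np.add.at(n_rl, ((rho[:-1] - 1).ravel(), (rho[1:] - 1).ravel()), 1)
    return n_rl


def update_xi(rho: np.ndarray, hp: Hyperparams,
              rng: np.random.Generator) -> np.ndarray:
    """Row-wise Dirichlet(delta + n_r.) draw of the transition matrix."""
    n_rl = transition_counts(rho)
    return np.stack([rng.dirichlet(hp.delta + n_rl[r]) for r in range(3)])


def update_mu_cluster(k: int, l: int, stats: SufficientStats,
                      params: ModelParams, hp: Hyperparams,
                      rng: np.random.Generator) -> float:
    """Draw mu_kl (k 0-based, l in {1, 2}).

    Under the constraint variant |mu_kl| is drawn from a normal left-truncated
    at t whose location uses the sign-matched statistic sign_l * M_kl, and the
    sign (+ for overexpressed, - for underexpressed) is restored on return.
    Without the constraint the draw is the untruncated conjugate normal.
    """
    li = l - 1
    s2 = float(params.sigma2_cluster[k, li])
    if s2 <= 0:
        raise ValueError("sigma2_cluster must be positive")
    M = float(stats.M_kl[k, li])
    N = float(stats.N_kl[k, li])
    sign = 1.0 if l == 1 else -1.0
    if hp.variant_constraint:
        loc, var = _mu_cluster_posterior(sign * M, N, s2, hp)
        draw = _truncnorm_draw(rng, hp.t, loc, math.sqrt(var))
        return float(sign * draw)
    loc, var = _mu_cluster_posterior(M, N, s2, hp)
    return float(rng.normal(loc, math.sqrt(var)))


def update_sigma2_cluster(k: int, l: int, stats: SufficientStats,
                          hp: Hyperparams, rng: np.random.Generator) -> float:
    """Inverse-gamma(a0 + N_kl/2, b0 + S2_kl/2) draw of sigma2_kl."""
    li = l - 1
    return float(_ig_draw(rng, hp.a0 + stats.N_kl[k, li] / 2.0,
                          hp.b0 + stats.S2_kl[k, li] / 2.0))


def update_sigma2_irrelevant(j: int, Y, state: LatentState, hp: Hyperparams,
                             rng: np.random.Generator) -> float:
    """Draw sigma2_j3 from the residuals of feature j over samples whose
    cluster currently marks j irrelevant (state-3 mean is 0)."""
    yv = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    in_state3 = state.rho[j, state.z - 1] == 3   # per sample i via its cluster
    N = int(in_state3.sum())
    S2 = float((yv[in_state3, j] ** 2).sum())
    return float(_ig_draw(rng, hp.a0 + N / 2.0, hp.b0 + S2 / 2.0))


def update_sigma2_feature(j: int, k: int, l: int, Y, state: LatentState,
                          params: ModelParams, hp: Hyperparams,
                          rng: np.random.Generator) -> float:
    """Draw sigma2_jkl from cluster-k residuals of feature j in state l."""
    yv = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    li = l - 1
    if state.rho[j, k] == l:
        members = state.z == (k + 1)
        resid = yv[members, j] - params.mu_feature[j, k, li]
        N, S2 = int(members.sum()), float((resid ** 2).sum())
    else:
        N, S2 = 0, 0.0
    return float(_ig_draw(rng, hp.a0 + N / 2.0, hp.b0 + S2 / 2.0))


def update_mu_feature(j: int, k: int, l: int, Y, state: LatentState,
                      params: ModelParams, hp: Hyperparams,
                      rng: np.random.Generator) -> float:
    """Conjugate normal draw of mu_jkl, shrunk toward the cluster mean mu_kl."""
    yv = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    li = l - 1
    if state.rho[j, k] == l:
        members = state.z == (k + 1)
        Mp, Np = float(yv[members, j].sum()), int(members.sum())
    else:
        Mp, Np = 0.0, 0
    mean, var = _mu_feature_posterior(params.mu_cluster[k, li],
                                      params.sigma2_cluster[k, li],
                                      params.sigma2_feature[j, k, li], Mp, Np)
    return float(rng.normal(mean, math.sqrt(var)))


def _state_loglik_matrix(k: int, nk: float, Ysum_k: np.ndarray,
                         Ysq_k: np.ndarray, params: ModelParams) -> np.ndarray:
    """(p, 3) per-feature data log-likelihood sums for cluster k's chain."""
    p = params.p
    L = np.empty((p, 3))
    for li in range(2):
        mu = params.mu_feature[:, k, li]
        s2 = params.sigma2_feature[:, k, li]
        quad = Ysq_k - 2.0 * mu * Ysum_k + nk * mu * mu
        L[:, li] = -0.5 * (nk * (LOG_2PI + np.log(s2)) + quad / s2)
    s2 = params.sigma2_irrelevant
    L[:, 2] = -0.5 * (nk * (LOG_2PI + np.log(s2)) + Ysq_k / s2)
    return L


def update_rho_column(k: int, Y, state: LatentState, params: ModelParams,
                      hp: Hyperparams, rng: np.random.Generator) -> np.ndarray:
    """One systematic scan of cluster k's feature-state chain (k 0-based).

    Site 1 couples only to its right neighbour (the uniform initial
    distribution cancels in the normalization), site p only to its left
    neighbour, interior sites to both.  Returns the new 1-based state column.
    Without the Markov variant the sites are sampled independently.
    """
    yv = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    members = state.z == (k + 1)
    nk = float(members.sum())
    Ysum_k = yv[members].sum(axis=0) if nk else np.zeros(yv.shape[1])
    Ysq_k = (yv[members] ** 2).sum(axis=0) if nk else np.zeros(yv.shape[1])
    L = _state_loglik_matrix(k, nk, Ysum_k, Ysq_k, params)

    if hp.variant_hmm:
        log_xi = np.asarray(_safe_log(params.xi))
        rho0 = np.ascontiguousarray(state.rho[:, k] - 1, dtype=np.int64)
        scan_chain(L, log_xi, rho0, rng.random(L.shape[0]))
        return rho0 + 1
    # independent categorical with uniform prior: Gumbel-max per site
    if not np.isfinite(L.max(axis=1)).all():
        bad = int(np.flatnonzero(~np.isfinite(L.max(axis=1)))[0])
        raise FloatingPointError(
            f"all state probabilities vanished at feature index {bad}")
    g = rng.gumbel(size=L.shape)
    return np.argmax(L + g, axis=1) + 1


def rho_site_conditional(j: int, k: int, Y, state: LatentState,
                         params: ModelParams, hp: Hyperparams) -> np.ndarray:
    """Exact conditional distribution of rho_{j,k} over states (1, 2, 3).

    The same factors the systematic scan samples from: the data term of
    feature j in cluster k and (under the Markov variant) the transition
    factors to the fixed neighbouring states.
    """
    yv = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    members = state.z == (k + 1)
    nk = float(members.sum())
    Ysum_k = yv[members].sum(axis=0)
    Ysq_k = (yv[members] ** 2).sum(axis=0)
    L = _state_loglik_matrix(k, nk, Ysum_k, Ysq_k, params)
    logw = L[j].copy()
    if hp.variant_hmm:
        log_xi = np.asarray(_safe_log(params.xi))
        if j > 0:
            logw += log_xi[state.rho[j - 1, k] - 1, :]
        if j < L.shape[0] - 1:
            logw += log_xi[:, state.rho[j + 1, k] - 1]
    m = logw.max()
    if not np.isfinite(m):
        raise FloatingPointError(
            f"all state probabilities vanished at feature index {j}")
    w = np.exp(logw - m)
    return w / w.sum()


def z_conditional(i: int, Y, state: LatentState,
                  params: ModelParams) -> np.ndarray:
    """Exact conditional distribution of z_i over the K clusters."""
    yv = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    logp = _z_logprob(yv[i:i + 1], state, params)[0]
    m = logp.max()
    if not np.isfinite(m):
        raise FloatingPointError(f"all cluster probabilities vanished for sample {i}")
    w = np.exp(logp - m)
    return w / w.sum()


def _z_logprob(yv: np.ndarray, state: LatentState,
               params: ModelParams) -> np.ndarray:
    """(n, K) unnormalized log conditional of the cluster labels."""
    mu, var = _assigned_mean_var(state, params)      # (p, K)
    inv = 1.0 / var
    const = -0.5 * (LOG_2PI + np.log(var)).sum(axis=0)       # (K,)
    quad = (yv * yv) @ inv - 2.0 * (yv @ (mu * inv)) + (mu * mu * inv).sum(axis=0)
    return np.asarray(_safe_log(params.omega))[None, :] + const[None, :] - 0.5 * quad


def update_z(Y, state: LatentState, params: ModelParams, hp: Hyperparams,
             rng: np.random.Generator) -> np.ndarray:
    """Draw every cluster label independently from its conditional (1-based)."""
    yv = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    logp = _z_logprob(yv, state, params)
    finite = np.isfinite(logp.max(axis=1))
    if not finite.all():
        raise FloatingPointError(
            f"all cluster probabilities vanished for sample {int(np.flatnonzero(~finite)[0])}")
    g = rng.gumbel(size=logp.shape)
    return np.argmax(logp + g, axis=1) + 1


# ---------------------------------------------------------------------------
# parameter log-prior (used for MAP scoring)

def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    norm = float(gammaln(alpha.sum()) - gammaln(alpha).sum())
    out = norm
    for xi_, ai in zip(np.asarray(x, float), np.asarray(alpha, float)):
        if ai != 1.0:
            lx = _safe_log(xi_)
            if not np.isfinite(lx):
                return -np.inf
            out += (ai - 1.0) * lx
    return out


def _ig_logpdf(x, a: float, b: float):
    x = np.asarray(x, float)
    return a * math.log(b) - gammaln(a) - (a + 1.0) * np.log(x) - b / x


def params_log_prior(state: LatentState, params: ModelParams,
                     hp: Hyperparams) -> float:
    """log prior density of the continuous parameters at the current draw.

    Includes the Dirichlet priors of Omega (and xi under the Markov variant),
    the (truncated) normal priors of mu_kl, the inverse-gamma priors of all
    variances, and the hierarchical normal prior of the mu_jkl that the
    current rho marks relevant.  Used only for ranking draws (MAP).
    """
    total = _dirichlet_logpdf(params.omega, hp.alpha)
    if hp.variant_hmm:
        for r in range(3):
            total += _dirichlet_logpdf(params.xi[r], hp.delta)
    sd0 = math.sqrt(hp.sigma2_mu0)
    log_tail = math.log1p(-0.5 * (1.0 + math.erf((hp.t - hp.mu0) / (sd0 * math.sqrt(2)))))
    for k in range(params.K):
        for li in range(2):
            mu = params.mu_cluster[k, li]
            if hp.variant_constraint:
                a = abs(mu)
                if a <= hp.t or (li == 0) != (mu > 0):
                    return -np.inf
                total += (-0.5 * (LOG_2PI + 2 * math.log(sd0)
                                  + ((a - hp.mu0) / sd0) ** 2) - log_tail)
            else:
                total += -0.5 * (LOG_2PI + 2 * math.log(sd0)
                                 + ((mu - hp.mu0) / sd0) ** 2)
    total += float(_ig_logpdf(params.sigma2_cluster, hp.a0, hp.b0).sum())
    total += float(_ig_logpdf(params.sigma2_irrelevant, hp.a0, hp.b0).sum())
    for li in range(2):
        mask = state.rho == (li + 1)
        if mask.any():
            mu = params.mu_feature[:, :, li]
            s2kl = params.sigma2_cluster[:, li][None, :]
            mukl = params.mu_cluster[:, li][None, :]
            lp = -0.5 * (LOG_2PI + np.log(s2kl) + (mu - mukl) ** 2 / s2kl)
            total += float(lp[mask].sum())
            total += float(_ig_logpdf(params.sigma2_feature[:, :, li][mask],
                                      hp.a0, hp.b0).sum())
    return float(total)


# ---------------------------------------------------------------------------
# the MCMC loop

@dataclass
class MCMCTrace:
    """Retained post-burn-in MCMC output.

    ``loglik`` holds the complete-data log-likelihood per retained draw,
    ``obs_loglik`` the observation term log p(y | theta, z, rho) entering the
    DIC, and ``log_prior`` the continuous-parameter prior used for MAP
    scoring.  The MAP draw itself is tracked online so that ``draws`` may be
    left unstored on large problems (``store_draws=False``).
    """

    loglik: np.ndarray
    obs_loglik: np.ndarray
    log_prior: np.ndarray
    mu_cluster_draws: np.ndarray       # (S, K, 2)
    n_empty_per_draw: np.ndarray       # clusters with zero members, per draw
    map_index: int
    map_state: LatentState
    map_params: ModelParams
    config: dict[str, Any]
    draws: list[tuple[LatentState, ModelParams]] | None = None

    @property
    def S(self) -> int:
        return len(self.loglik)


class _GibbsRunner:
    """Vectorized sampler state for one run (internal)."""

    def __init__(self, Y: ExpressionMatrix, hp: Hyperparams,
                 rng: np.random.Generator):
        self.yv = Y.values
        self.ysq = self.yv * self.yv
        self.hp = hp
        self.rng = rng
        n, p = self.yv.shape
        self.n, self.p, self.K = n, p, hp.K
        # Latents start uniform at random, as the sampling scheme prescribes.
        self.z0 = rng.integers(0, hp.K, size=n)
        self.rho0 = rng.integers(0, 3, size=(p, hp.K))
        # Continuous parameters (consumed before their first update) start at
        # neutral, cluster-exchangeable values: unit-scale variances (b0/a0)
        # and cluster means one standardized unit out.  Identical values
        # across clusters keep the first label update symmetric; a cluster
        # whose parameters start far out (e.g. prior draws from the diffuse
        # mean prior) loses every sample on the first sweep and an empty
        # cluster cannot win samples back.
        self.omega = np.full(hp.K, 1.0 / hp.K)
        self.xi = np.full((3, 3), 1.0 / 3.0)
        s2_init = hp.b0 / hp.a0
        self.sigma2_cluster = np.full((hp.K, 2), s2_init)
        self.sigma2_feature = np.full((p, hp.K, 2), s2_init)
        self.sigma2_irrelevant = np.full(p, s2_init)
        m_init = max(1.0, hp.t)
        self.mu_cluster = np.tile(np.array([m_init, -m_init]), (hp.K, 1))
        self.mu_feature = np.zeros((p, hp.K, 2))

    # -- cached per-cluster data sums ------------------------------------
    def _refresh_cluster_sums(self) -> None:
        C = np.zeros((self.n, self.K))
        C[np.arange(self.n), self.z0] = 1.0
        self.nk = C.sum(axis=0)
        self.Ysum = self.yv.T @ C
        self.Ysq = self.ysq.T @ C

    def params(self) -> ModelParams:
        return ModelParams(self.omega.copy(), self.xi.copy(),
                           self.mu_cluster.copy(), self.sigma2_cluster.copy(),
                           self.mu_feature.copy(), self.sigma2_feature.copy(),
                           self.sigma2_irrelevant.copy())

    def state(self) -> LatentState:
        return LatentState(self.z0 + 1, self.rho0 + 1)

    def step(self) -> None:
        hp, rng = self.hp, self.rng
        self._refresh_cluster_sums()
        rel_mask = np.stack([self.rho0 == 0, self.rho0 == 1], axis=2)  # (p,K,2)

        # cluster probabilities
        self.omega = rng.dirichlet(hp.alpha + self.nk)

        # per-feature means (conjugate normals, all j, k, l at once)
        Np = self.nk[None, :, None] * rel_mask
        Mp = self.Ysum[:, :, None] * rel_mask
        mean, var = _mu_feature_posterior(self.mu_cluster[None, :, :],
                                          self.sigma2_cluster[None, :, :],
                                          self.sigma2_feature, Mp, Np)
        self.mu_feature = mean + np.sqrt(var) * rng.standard_normal(mean.shape)

        # cluster-level means
        M_kl = (rel_mask * self.mu_feature).sum(axis=0)
        N_kl = rel_mask.sum(axis=0)
        if hp.variant_constraint:
            signs = np.array([1.0, -1.0])[None, :]
            loc, var = _mu_cluster_posterior(signs * M_kl, N_kl,
                                             self.sigma2_cluster, hp)
            self.mu_cluster = signs * _truncnorm_draw(rng, hp.t, loc, np.sqrt(var))
        else:
            loc, var = _mu_cluster_posterior(M_kl, N_kl, self.sigma2_cluster, hp)
            self.mu_cluster = rng.normal(loc, np.sqrt(var))

        # variances
        S2_kl = (rel_mask * (self.mu_feature
                             - self.mu_cluster[None, :, :]) ** 2).sum(axis=0)
        self.sigma2_cluster = _ig_draw(rng, hp.a0 + N_kl / 2.0,
                                       hp.b0 + S2_kl / 2.0)
        quad = (self.Ysq[:, :, None]
                - 2.0 * self.mu_feature * self.Ysum[:, :, None]
                + self.nk[None, :, None] * self.mu_feature ** 2)
        self.sigma2_feature = _ig_draw(rng, hp.a0 + Np / 2.0,
                                       hp.b0 + np.where(rel_mask, quad, 0.0) / 2.0)
        irr = self.rho0 == 2
        N3 = (irr * self.nk[None, :]).sum(axis=1)
        S3 = (irr * self.Ysq).sum(axis=1)
        self.sigma2_irrelevant = _ig_draw(rng, hp.a0 + N3 / 2.0,
                                          hp.b0 + S3 / 2.0)

        # transition matrix
        if hp.variant_hmm:
            n_rl = transition_counts(self.rho0 + 1)
            self.xi = np.stack([rng.dirichlet(hp.delta + n_rl[r])
                                for r in range(3)])

        # cluster labels
        params = self.params()
        state = self.state()
        self.z0 = update_z(self.yv, state, params, hp, rng) - 1
        self._refresh_cluster_sums()

        # feature-state chains
        if hp.variant_hmm:
            log_xi = np.asarray(_safe_log(self.xi))
            for k in range(self.K):
                L = _state_loglik_matrix(k, self.nk[k], self.Ysum[:, k],
                                         self.Ysq[:, k], params)
                col = np.ascontiguousarray(self.rho0[:, k])
                scan_chain(L, log_xi, col, rng.random(self.p))
                self.rho0[:, k] = col
        else:
            for k in range(self.K):
                L = _state_loglik_matrix(k, self.nk[k], self.Ysum[:, k],
                                         self.Ysq[:, k], params)
                g = rng.gumbel(size=L.shape)
                self.rho0[:, k] = np.argmax(L + g, axis=1)


def run_gibbs(Y: ExpressionMatrix | np.ndarray, hp: Hyperparams, iters: int,
              burn_in: int, seed: int, thin: int = 1,
              store_draws: bool = True) -> MCMCTrace:
    """Run the full Gibbs sampler and retain post-burn-in draws.

    Latents start from uniform random assignments and the continuous
    parameters from their priors.  ``store_draws=False`` keeps only the
    log-likelihood series, the mu_kl series and the MAP draw — enough for
    MAP summaries and DIC on large problems.
    """
    if not isinstance(Y, ExpressionMatrix):
        Y = ExpressionMatrix(np.asarray(Y, dtype=float))
    if burn_in < 0 or iters <= burn_in:
        raise ValueError("need iters > burn_in >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")

    rng = np.random.default_rng(seed)
    runner = _GibbsRunner(Y, hp, rng)

    loglik, obs_ll, log_prior, mu_draws, n_empty = [], [], [], [], []
    draws: list[tuple[LatentState, ModelParams]] | None = [] if store_draws else None
    best = -np.inf
    map_index, map_state, map_params = 0, runner.state(), runner.params()

    for it in range(iters):
        runner.step()
        if (it + 1) % 100 == 0 and logger.isEnabledFor(logging.INFO):
            state, params = runner.state(), runner.params()
            logger.info("iteration %d/%d: complete-data log-likelihood %.2f",
                        it + 1, iters, complete_loglik(Y, state, params, hp))
        if it < burn_in or (it - burn_in) % thin:
            continue
        state, params = runner.state(), runner.params()
        ll = complete_loglik(Y, state, params, hp)
        obs = observed_loglik(Y, state, params)
        lp = params_log_prior(state, params, hp)
        loglik.append(ll)
        obs_ll.append(obs)
        log_prior.append(lp)
        mu_draws.append(params.mu_cluster.copy())
        n_empty.append(int((runner.nk == 0).sum()))
        score = ll + lp
        if score > best:
            best = score
            map_index = len(loglik) - 1
            map_state, map_params = state, params
        if draws is not None:
            draws.append((state, params))

    n_empty_arr = np.asarray(n_empty, dtype=int)
    if (n_empty_arr > 0).any():
        logger.warning("%d of %d retained draws had at least one empty cluster",
                       int((n_empty_arr > 0).sum()), len(n_empty))
    return MCMCTrace(
        loglik=np.asarray(loglik), obs_loglik=np.asarray(obs_ll),
        log_prior=np.asarray(log_prior),
        mu_cluster_draws=np.asarray(mu_draws),
        n_empty_per_draw=n_empty_arr,
        map_index=map_index, map_state=map_state, map_params=map_params,
        config={"hp": hp, "iters": iters, "burn_in": burn_in,
                "seed": seed, "thin": thin},
        draws=draws,
    )
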