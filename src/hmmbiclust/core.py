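"""Domain types, hyperparameters, sufficient statistics and likelihood evaluation.

The model biclusters an n x p expression matrix (samples in rows, features in
columns, features pre-ordered by biological similarity).  Each sample belongs
to one of K clusters (label ``z_i``); within cluster k every feature j carries
a latent state ``rho_{j,k}``:

* state 1 — overexpressed   (mean ``mu_{jk1}`` drawn around a cluster-level
  positive mean ``mu_{k1}``),
* state 2 — underexpressed  (mean around a negative ``mu_{k2}``),
* state 3 — irrelevant      (mean fixed at 0, variance ``sigma2_{j3}`` shared
  across clusters).

Along the ordered feature axis the states of consecutive features follow a
first-order Markov chain with a 3 x 3 transition matrix ``xi`` shared across
clusters, so neighbouring (functionally similar) genes are encouraged to share
a state.  Each (cluster, state) rectangle is a bicluster: 3K in total.

State labels are 1-based (1, 2, 3) in all public containers, matching the
model notation; sampler internals use 0-based arrays (state 3 -> index 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "LatentState",
    "ModelParams",
    "Hyperparams",
    "SufficientStats",
    "observation_loglik",
    "complete_loglik",
    "sufficient_stats",
]

#: probabilities below this clamp to -inf in log space
_PROB_FLOOR = 1e-300

LOG_2PI = math.log(2.0 * math.pi)


def _safe_log(x: np.ndarray | float) -> np.ndarray | float:
    """Elementwise log with probabilities below 1e-300 mapped to -inf."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, -np.inf)
    good = x >= _PROB_FLOOR
    with np.errstate(divide="ignore"):
        out[good] = np.log(x[good])
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class ExpressionMatrix:
    """n x p real matrix with identifiers; samples in rows, features in columns.

    ``feature_order`` records the permutation of the original column order that
    produced the current (biologically ordered) layout; the Markov chain always
    runs over the stored column order.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)
    feature_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValueError("matrix must have at least one sample and one feature")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"sample{i + 1}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"feature{j + 1}" for j in range(p)]
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise ValueError("identifier lengths do not match matrix shape")
        if self.feature_order is None:
            self.feature_order = np.arange(p)
        self.feature_order = np.asarray(self.feature_order, dtype=int)
        if sorted(self.feature_order.tolist()) != list(range(p)):
            raise ValueError("feature_order is not a permutation of 0..p-1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class LatentState:
    """Cluster labels z (1..K) and feature-state matrix rho (p x K, values 1..3)."""

    z: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=int)
        self.rho = np.asarray(self.rho, dtype=int)
        if self.z.ndim != 1 or self.rho.ndim != 2:
            raise ValueError("z must be 1-d and rho 2-d (p x K)")
        if self.z.min(initial=1) < 1:
            raise ValueError("cluster labels are 1-based")
        if not np.isin(self.rho, (1, 2, 3)).all():
            raise ValueError("feature states must be in {1, 2, 3}")

    @property
    def K(self) -> int:
        return self.rho.shape[1]

    def copy(self) -> "LatentState":
        return LatentState(self.z.copy(), self.rho.copy())


@dataclass
class ModelParams:
    """Continuous model parameters.

    ``mu_feature`` holds per-feature means for states 1 and 2 only (p x K x 2);
    the state-3 mean is identically 0 and is represented implicitly.
    ``sigma2_irrelevant`` (length p) is the state-3 variance, shared across k.
    """

    omega: np.ndarray            # (K,) cluster probabilities
    xi: np.ndarray               # (3, 3) row-stochastic transition matrix
    mu_cluster: np.ndarray       # (K, 2) cluster-level means mu_k1, mu_k2
    sigma2_cluster: np.ndarray   # (K, 2)
    mu_feature: np.ndarray       # (p, K, 2)
    sigma2_feature: np.ndarray   # (p, K, 2)
    sigma2_irrelevant: np.ndarray  # (p,)

    def __post_init__(self) -> None:
        for name in ("omega", "xi", "mu_cluster", "sigma2_cluster",
                     "mu_feature", "sigma2_feature", "sigma2_irrelevant"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def validate(self) -> None:
        if not math.isclose(self.omega.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("omega must sum to 1")
        if not np.allclose(self.xi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of xi must sum to 1")
        if (self.omega < 0).any() or (self.xi < 0).any():
            raise ValueError("probabilities must be nonnegative")
        for name in ("sigma2_cluster", "sigma2_feature", "sigma2_irrelevant"):
            if (getattr(self, name) <= 0).any():
                raise ValueError(f"{name} must be strictly positive")

    def copy(self) -> "ModelParams":
        return ModelParams(*(np.copy(getattr(self, f)) for f in (
            "omega", "xi", "mu_cluster", "sigma2_cluster",
            "mu_feature", "sigma2_feature", "sigma2_irrelevant")))

    @property
    def K(self) -> int:
        return self.omega.shape[0]

    @property
    def p(self) -> int:
        return self.mu_feature.shape[0]

    def state_means(self) -> np.ndarray:
        """p x K matrix of per-feature means given a state assignment of 3 is 0.

        Helper returning mu_feature stacked with the implicit zero plane:
        shape (p, K, 3)."""
        zero = np.zeros(self.mu_feature.shape[:2] + (1,))
        return np.concatenate([self.mu_feature, zero], axis=2)


@dataclass
class Hyperparams:
    """Fixed prior settings and model-variant switches.

    Defaults follow the simulation-study settings: truncation ``t=0.2``,
    diffuse cluster-mean prior (mu0=0, sigma2_mu0=1000), inverse-gamma(1, 1)
    variance priors, uniform Dirichlet priors (alpha_k = delta_l = 1) and a
    uniform initial state distribution v.
    """

    K: int = 2
    alpha: np.ndarray | None = None   # Dirichlet prior for omega, default 1s
    delta: np.ndarray | None = None   # Dirichlet prior for xi rows, default 1s
    t: float = 0.2
    mu0: float = 0.0
    sigma2_mu0: float = 1000.0
    a0: float = 1.0
    b0: float = 1.0
    v: np.ndarray | None = None       # initial state distribution, default uniform
    variant_hmm: bool = True          # Markov prior on feature states
    variant_constraint: bool = True   # sign/truncation constraint on mu_kl

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        self.alpha = (np.ones(self.K) if self.alpha is None
                      else np.asarray(self.alpha, dtype=float))
        self.delta = (np.ones(3) if self.delta is None
                      else np.asarray(self.delta, dtype=float))
        self.v = (np.full(3, 1.0 / 3.0) if self.v is None
                  else np.asarray(self.v, dtype=float))
        if self.alpha.shape != (self.K,) or (self.alpha <= 0).any():
            raise ValueError("alpha must be K positive reals")
        if self.delta.shape != (3,) or (self.delta <= 0).any():
            raise ValueError("delta must be 3 positive reals")
        if self.v.shape != (3,) or not math.isclose(self.v.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("v must be a length-3 simplex vector")
        for name in ("t", "sigma2_mu0", "a0", "b0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SufficientStats:
    """Sufficient statistics of the full conditionals.

    ``M_kl[k, l-1] = sum_j I(rho_jk = l) mu_jkl`` and ``N_kl`` the matching
    counts; ``S2_kl`` the squared deviations of mu_jkl around mu_kl;
    ``n_rl`` the pooled state-transition counts along the ordered feature axis;
    ``Mprime_jkl``/``Nprime_k`` the per-(feature, cluster) data sums and
    cluster sizes entering the mu_jkl update.
    """

    M_kl: np.ndarray        # (K, 2)
    N_kl: np.ndarray        # (K, 2) ints
    S2_kl: np.ndarray       # (K, 2)
    n_rl: np.ndarray        # (3, 3) ints
    Mprime_jkl: np.ndarray  # (p, K, 2) sums of y over cluster members where rho=l
    Nprime_k: np.ndarray    # (K,) cluster sizes
    Ysq_jk: np.ndarray      # (p, K) sums of y^2 over cluster members


def observation_loglik(y: float, mu: float, sigma2: float) -> float:
    """Log normal density of one observation given its mean and variance."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be strictly positive")
    return -0.5 * (LOG_2PI + math.log(sigma2) + (y - mu) ** 2 / sigma2)


def _assigned_mean_var(state: LatentState, params: ModelParams):
    """p x K arrays of the mean and variance implied by the current rho."""
    rho = state.rho
    mu = np.where(rho == 1, params.mu_feature[:, :, 0],
                  np.where(rho == 2, params.mu_feature[:, :, 1], 0.0))
    var = np.where(rho == 1, params.sigma2_feature[:, :, 0],
                   np.where(rho == 2, params.sigma2_feature[:, :, 1],
                            params.sigma2_irrelevant[:, None]))
    return mu, var


def observed_loglik(Y: ExpressionMatrix | np.ndarray, state: LatentState,
                    params: ModelParams) -> float:
    """log p(y | theta, z, rho): the observation part of the likelihood."""
    yv = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    mu, var = _assigned_mean_var(state, params)
    z0 = state.z - 1
    m = mu[:, z0].T        # (n, p)
    v = var[:, z0].T
    resid = yv - m
    return float(-0.5 * np.sum(LOG_2PI + np.log(v) + resid * resid / v))


def latent_log_prior(state: LatentState, params: ModelParams,
                     hp: Hyperparams) -> float:
    """log p(rho, z | theta): each cluster's state chain counted once, plus
    the cluster-membership probabilities of all samples.

    The per-cluster chain counting is the factorisation the sampling kernels
    imply (the label conditional carries no chain factor; the site
    conditionals carry single transition factors), and it gives empty
    clusters' chains a well-defined prior.
    """
    z0 = state.z - 1
    rho0 = state.rho - 1
    K = state.K
    counts = np.bincount(z0, minlength=K).astype(float)

    log_omega = _safe_log(params.omega)
    total = 0.0
    for k in range(K):
        if counts[k] == 0:
            continue
        if not np.isfinite(log_omega[k]):
            return -np.inf
        total += counts[k] * log_omega[k]

    if hp.variant_hmm:
        log_v = _safe_log(hp.v)
        log_xi = _safe_log(params.xi)
        for k in range(K):
            chain = log_v[rho0[0, k]]
            if rho0.shape[0] > 1:
                chain += log_xi[rho0[:-1, k], rho0[1:, k]].sum()
            if not np.isfinite(chain):
                return -np.inf
            total += chain
    else:
        # independent uniform categorical states
        total += rho0.size * math.log(1.0 / 3.0)
    return float(total)


def complete_loglik(Y: ExpressionMatrix | np.ndarray, state: LatentState,
                    params: ModelParams, hp: Hyperparams) -> float:
    """Complete-data log-likelihood log p(y, rho, z | theta).

    The K state-chain priors, the cluster membership probabilities, and the
    observation terms.  Zero-probability entries met with positive count
    yield -inf, never an exception.
    """
    lp = latent_log_prior(state, params, hp)
    if not np.isfinite(lp):
        return -np.inf
    return lp + observed_loglik(Y, state, params)


def sufficient_stats(Y: ExpressionMatrix | np.ndarray, state: LatentState,
                     params: ModelParams) -> SufficientStats:
    """All sufficient statistics of the conjugate full conditionals."""
    yv = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    n, p = yv.shape
    K = state.K
    rho = state.rho
    z0 = state.z - 1

    C = np.zeros((n, K))
    C[np.arange(n), z0] = 1.0
    Nprime_k = C.sum(axis=0)
    Ysum = yv.T @ C                    # (p, K)
    Ysq = (yv * yv).T @ C              # (p, K)

    M_kl = np.zeros((K, 2))
    N_kl = np.zeros((K, 2), dtype=int)
    S2_kl = np.zeros((K, 2))
    Mprime = np.zeros((p, K, 2))
    for li in range(2):
        mask = rho == (li + 1)
        M_kl[:, li] = (mask * params.mu_feature[:, :, li]).sum(axis=0)
        N_kl[:, li] = mask.sum(axis=0)
        dev = (params.mu_feature[:, :, li] - params.mu_cluster[:, li][None, :]) ** 2
        S2_kl[:, li] = (mask * dev).sum(axis=0)
        Mprime[:, :, li] = mask * Ysum

    n_rl = np.zeros((3, 3), dtype=int)
    if p > 1:
        r = (rho[:-1, :] - 1).ravel()
        s = (rho[1:, :] - 1).ravel()
        np.add.at(n_rl, (r, s), 1)

    return SufficientStats(M_kl=M_kl, N_kl=N_kl, S2_kl=S2_kl, n_rl=n_rl,
                           Mprime_jkl=Mprime, Nprime_k=Nprime_k, Ysq_jk=Ysq)
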