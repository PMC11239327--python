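"""DIC over a grid of cluster counts K.

The criterion is estimated from the MCMC output as

    DIC = -(4/S) * sum_s log p(y | theta_s, z_s, rho_s)
          + 2 * log p(y | theta~, z~, rho~),

with the second term evaluated at the joint MAP draw.  The deviance terms
condition on the sampled latents (the marginal over z and rho is
intractable).  Lower is better; the scan reports the curve and empty-cluster
diagnostics, leaving the elbow rule to the user: K values past the elbow tend
to produce clusters with few or zero members and should not be selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .core import ExpressionMatrix, Hyperparams
from .gibbs import MCMCTrace, run_gibbs
from .summarize import map_estimate

__all__ = ["DICResult", "compute_dic", "dic_scan"]


@dataclass
class DICResult:
    K: int
    dic: float
    mean_deviance_term: float   # -(4/S) sum of per-draw observation log-lik
    map_term: float             # 2 * observation log-lik at the MAP draw
    n_empty_cluster_draws: int  # retained draws with at least one empty cluster
    min_map_cluster_size: int   # smallest cluster of the MAP partition


def compute_dic(trace: MCMCTrace) -> DICResult:
    """DIC of one fitted run, from the stored observation log-likelihoods."""
    if trace.S < 1:
        raise ValueError("empty trace")
    obs = trace.obs_loglik
    if not np.isfinite(obs).all():
        warnings.warn("non-finite log-likelihood among draws; DIC is +inf",
                      stacklevel=2)
        mean_term, map_term = np.inf, np.inf
    else:
        est = map_estimate(trace)
        mean_term = -4.0 * float(obs.mean())
        map_term = 2.0 * float(obs[est.map_index])
    est = map_estimate(trace)
    counts = np.bincount(est.z_hat - 1, minlength=est.K)
    return DICResult(
        K=int(trace.config["hp"].K),
        dic=mean_term + map_term,
        mean_deviance_term=mean_term,
        map_term=map_term,
        n_empty_cluster_draws=int((trace.n_empty_per_draw > 0).sum()),
        min_map_cluster_size=int(counts.min()),
    )


def _derived_seed(seed: int, K: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(K,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def dic_scan(Y: ExpressionMatrix, hp_base: Hyperparams, K_grid: list[int],
             iters: int, burn_in: int, seed: int) -> list[DICResult]:
    """Fit once per K and return the DIC curve.

    The per-K seed is derived from (seed, K) only, so permuting the grid
    permutes the results identically.
    """
    if not K_grid:
        raise ValueError("K_grid must be nonempty")
    out = []
    for K in K_grid:
        hp = replace(hp_base, K=K, alpha=None)
        trace = run_gibbs(Y, hp, iters=iters, burn_in=burn_in,
                          seed=_derived_seed(seed, K), store_draws=False)
        out.append(compute_dic(trace))
    return out
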