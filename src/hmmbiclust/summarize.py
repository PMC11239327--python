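"""Point estimates from an MCMC trace and bicluster extraction.

The point summary is the joint MAP: the single retained draw maximizing the
complete-data log-likelihood plus the continuous-parameter log prior.  Using
one draw keeps z, rho and the parameters internally consistent and sidesteps
label switching across draws (no relabeling algorithm is applied — a single
draw needs none).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ModelParams
from .f1 import Bicluster
from .gibbs import MCMCTrace

__all__ = ["PointEstimate", "map_estimate", "extract_biclusters",
           "align_variant_labels"]


@dataclass
class PointEstimate:
    """An internally consistent (z, rho, params) triple from one MCMC draw."""

    z_hat: np.ndarray        # (n,) labels 1..K
    rho_hat: np.ndarray      # (p, K) states 1..3
    params_hat: ModelParams
    map_index: int

    @property
    def K(self) -> int:
        return self.rho_hat.shape[1]


def map_estimate(trace: MCMCTrace, score: str = "posterior") -> PointEstimate:
    """The retained draw with the highest joint score (ties: earliest index).

    ``score="posterior"`` ranks draws by complete-data log-likelihood plus
    parameter log prior (the default); ``score="loglik"`` ranks by likelihood
    alone and requires stored draws.
    """
    if trace.S < 1:
        raise ValueError("empty trace")
    if score == "posterior":
        idx = int(np.argmax(trace.loglik + trace.log_prior))
        if idx == trace.map_index or trace.draws is None:
            state, params = trace.map_state, trace.map_params
            idx = trace.map_index
        else:
            state, params = trace.draws[idx]
    elif score == "loglik":
        if trace.draws is None:
            raise ValueError("likelihood-only MAP scoring requires stored draws")
        idx = int(np.argmax(trace.loglik))
        state, params = trace.draws[idx]
    else:
        raise ValueError(f"unknown score {score!r}")
    return PointEstimate(z_hat=state.z.copy(), rho_hat=state.rho.copy(),
                         params_hat=params.copy(), map_index=idx)


def extract_biclusters(est: PointEstimate,
                       min_cluster_size: int = 3) -> list[Bicluster]:
    """Three rectangles (over / under / irrelevant) per retained cluster.

    Clusters with fewer than ``min_cluster_size`` samples are discarded,
    mirroring the practice of dropping clusters of size < 3 in applications;
    pass 0 to always keep all 3K rectangles.
    """
    out: list[Bicluster] = []
    for k in range(1, est.K + 1):
        members = np.flatnonzero(est.z_hat == k)
        if members.size < min_cluster_size:
            continue
        samples = frozenset(members.tolist())
        for l in (1, 2, 3):
            feats = frozenset(np.flatnonzero(est.rho_hat[:, k - 1] == l).tolist())
            out.append(Bicluster(samples=samples, features=feats))
    return out


def align_variant_labels(est: PointEstimate) -> PointEstimate:
    """Resolve the state-1/state-2 label ambiguity of unconstrained fits.

    Within each cluster, relabels the two relevant states so that state 1
    carries the larger cluster-level mean.  Constrained estimates (mu_k1 > 0 >
    mu_k2 by construction) pass through unchanged; the operation is
    idempotent.
    """
    params = est.params_hat.copy()
    rho = est.rho_hat.copy()
    for k in range(est.K):
        if params.mu_cluster[k, 0] >= params.mu_cluster[k, 1]:
            continue
        params.mu_cluster[k, :] = params.mu_cluster[k, ::-1]
        params.sigma2_cluster[k, :] = params.sigma2_cluster[k, ::-1]
        params.mu_feature[:, k, :] = params.mu_feature[:, k, ::-1]
        params.sigma2_feature[:, k, :] = params.sigma2_feature[:, k, ::-1]
        col = rho[:, k]
        one, two = col == 1, col == 2
        col[one], col[two] = 2, 1
    return PointEstimate(z_hat=est.z_hat.copy(), rho_hat=rho,
                         params_hat=params, map_index=est.map_index)
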