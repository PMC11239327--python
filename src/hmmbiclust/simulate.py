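"""Synthetic expression data with known ground-truth biclusters.

Two generators mirror the simulation study conditions:

* Setting 1 — the first 100 ordered features are overexpressed (state 1) and
  the next 100 underexpressed (state 2) in every cluster; the remaining
  p - 200 features are irrelevant.  Ordered relevant blocks are exactly the
  regime the Markov state prior is designed to exploit.
* Setting 2 — the same 100 + 100 relevant features are placed uniformly at
  random among the p positions (shared across clusters), removing the
  ordering signal.

Observations are ``y_ij = mu_{k,l} + eps``, ``eps ~ Normal(0, sigma2)`` with
cluster means ``mu_k1 = (k+1)/2``, ``mu_k2 = -(k+1)/2`` and ``mu_k3 = 0``,
so cluster 1 has relevant-block means +1 / -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ExpressionMatrix, LatentState
from .f1 import Bicluster

__all__ = ["SimulationTruth", "simulate", "truth_to_biclusters"]

#: number of overexpressed (and underexpressed) features in the default design
BLOCK = 100


@dataclass
class SimulationTruth:
    """Ground truth of one simulated data set."""

    z_true: np.ndarray       # (n,) labels 1..K
    rho_true: np.ndarray     # (p, K) states 1..3
    mu_true: np.ndarray      # (K, 3) state means per cluster
    sigma2_true: float
    setting: int
    seed: int

    @property
    def K(self) -> int:
        return self.rho_true.shape[1]

    def latent_state(self) -> LatentState:
        return LatentState(self.z_true.copy(), self.rho_true.copy())


def _cluster_assignment(n: int, K: int, balanced: bool,
                        rng: np.random.Generator) -> np.ndarray:
    if balanced:
        # first ceil(n/K) samples to cluster 1, next block to cluster 2, ...
        size = -(-n // K)
        z = 1 + np.repeat(np.arange(K), size)[:n]
    else:
        z = 1 + rng.integers(0, K, size=n)
    return z.astype(int)


def simulate(n: int, K: int, p: int = 1000, sigma2: float = 1.0,
             setting: int = 1, seed: int = 0,
             balanced: bool = True) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Generate one data set with 100 overexpressed and 100 underexpressed features.

    Parameters
    ----------
    n, K, p
        Samples, clusters, features (p >= 200 so the two relevant blocks fit).
    sigma2
        Homoscedastic noise variance (1 or 2 in the reference scenarios).
    setting
        1 = ordered relevant blocks, 2 = randomly placed relevant features.
    balanced
        Deterministic near-equal cluster sizes (default) or multinomial(1/K).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if setting not in (1, 2):
        raise ValueError("setting must be 1 or 2")
    if p < 2 * BLOCK:
        raise ValueError(f"p must be at least {2 * BLOCK} to hold the relevant blocks")
    if n < K:
        raise ValueError("need at least one sample per cluster")

    rng = np.random.default_rng(seed)
    z = _cluster_assignment(n, K, balanced, rng)

    # identical state columns across clusters; only the means differ by k
    states = np.full(p, 3, dtype=int)
    if setting == 1:
        pos = np.arange(2 * BLOCK)
    else:
        pos = rng.choice(p, size=2 * BLOCK, replace=False)
    states[pos[:BLOCK]] = 1
    states[pos[BLOCK:]] = 2
    rho = np.repeat(states[:, None], K, axis=1)

    ks = np.arange(1, K + 1)
    mu_true = np.stack([(ks + 1) / 2.0, -(ks + 1) / 2.0, np.zeros(K)], axis=1)

    means = mu_true[(z - 1)[:, None], (states - 1)[None, :]]
    Y = means + rng.normal(0.0, np.sqrt(sigma2), size=(n, p))

    M = ExpressionMatrix(Y)
    truth = SimulationTruth(z_true=z, rho_true=rho, mu_true=mu_true,
                            sigma2_true=float(sigma2), setting=setting, seed=seed)
    return M, truth


def truth_to_biclusters(truth: SimulationTruth) -> list[Bicluster]:
    """The 3K true rectangles: (samples with z=k, features with rho_jk=l)."""
    out: list[Bicluster] = []
    for k in range(1, truth.K + 1):
        samples = frozenset(np.flatnonzero(truth.z_true == k).tolist())
        for l in (1, 2, 3):
            feats = frozenset(np.flatnonzero(truth.rho_true[:, k - 1] == l).tolist())
            out.append(Bicluster(samples=samples, features=feats))
    return out
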