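"""Single-site systematic scan of one cluster's feature-state chain.

The conditional of site j couples to its neighbours only through the
transition matrix, so the scan must run sequentially j = 1..p.  The hot loop
is compiled with numba when available; a pure-python twin (used as a fallback
and as an independent reference in tests) implements the identical arithmetic.

Contract: ``L`` is the (p, 3) matrix of per-state data log-likelihood sums for
the cluster, ``log_xi`` the log transition matrix, ``rho`` the 0-based state
column updated in place, ``u`` one uniform per site.  Returns -1 on success or
the index of the first site whose three conditional weights were all -inf.
"""

from __future__ import annotations

import math

import numpy as np


def _scan_chain_py(L, log_xi, rho, u):  # pragma: no cover - mirrored by njit twin
    p = L.shape[0]
    for j in range(p):
        w0 = L[j, 0]
        w1 = L[j, 1]
        w2 = L[j, 2]
        if j > 0:
            r = rho[j - 1]
            w0 += log_xi[r, 0]
            w1 += log_xi[r, 1]
            w2 += log_xi[r, 2]
        if j < p - 1:
            s = rho[j + 1]
            w0 += log_xi[0, s]
            w1 += log_xi[1, s]
            w2 += log_xi[2, s]
        m = w0
        if w1 > m:
            m = w1
        if w2 > m:
            m = w2
        if m == -math.inf:
            return j
        e0 = math.exp(w0 - m)
        e1 = math.exp(w1 - m)
        e2 = math.exp(w2 - m)
        r_ = u[j] * (e0 + e1 + e2)
        if r_ < e0:
            rho[j] = 0
        elif r_ < e0 + e1:
            rho[j] = 1
        else:
            rho[j] = 2
    return -1


try:  # numba accelerates the scan ~100x; the fallback is exact
    from numba import njit

    _scan_chain = njit(cache=False)(_scan_chain_py)
    # trigger compilation lazily on first real call
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _scan_chain = _scan_chain_py
    HAVE_NUMBA = False


def scan_chain(L: np.ndarray, log_xi: np.ndarray, rho: np.ndarray,
               u: np.ndarray) -> None:
    """Run one systematic scan, raising if a site has no admissible state."""
    bad = _scan_chain(L, log_xi, rho, u)
    if bad >= 0:
        raise FloatingPointError(
            f"all state probabilities vanished at feature index {bad}")
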