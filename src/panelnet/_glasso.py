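"""Block coordinate-descent graphical lasso kernel (numba-compiled).

Solves  max_K  log det K − tr(S·K) − λ·Σ_{i≠j}|K_ij|  by sweeping over
columns of the working covariance W and solving each column's lasso
sub-problem by coordinate descent (the classic "glasso" block algorithm,
with the diagonal left unpenalized so diag(W) = diag(S)).  Convergence is
declared on the duality gap  tr(S·K) − p + λ·Σ_{i≠j}|K_ij| < tol.

The kernel is warm-startable (W and Beta are carried across calls), which is
what makes EBIC grids inside permutation and bootstrap loops affordable.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _glasso_sweep(S, lam, W, Beta, inner_tol, inner_max):
    """One full sweep of column updates; mutates W and Beta in place."""
    p = S.shape[0]
    oth = np.empty(p - 1, dtype=np.int64)
    for j in range(p):
        for k in range(p - 1):
            oth[k] = k if k < j else k + 1
        beta = Beta[:, j]
        for _ in range(inner_max):
            max_delta = 0.0
            for k in range(p - 1):
                ik = oth[k]
                r = S[ik, j]
                for l in range(p - 1):
                    if l != k:
                        r -= W[ik, oth[l]] * beta[l]
                if r > lam:
                    b_new = (r - lam) / W[ik, ik]
                elif r < -lam:
                    b_new = (r + lam) / W[ik, ik]
                else:
                    b_new = 0.0
                d = abs(b_new - beta[k])
                if d > max_delta:
                    max_delta = d
                beta[k] = b_new
            if max_delta < inner_tol:
                break
        for k in range(p - 1):
            ik = oth[k]
            w = 0.0
            for l in range(p - 1):
                w += W[ik, oth[l]] * beta[l]
            W[ik, j] = w
            W[j, ik] = w


@njit(cache=True)
def _assemble_K(W, Beta):
    """Precision from the working covariance and per-column lasso coefficients."""
    p = W.shape[0]
    K = np.zeros((p, p))
    for j in range(p):
        denom = W[j, j]
        for k in range(p - 1):
            ik = k if k < j else k + 1
            denom -= W[ik, j] * Beta[k, j]
        kjj = 1.0 / denom
        K[j, j] = kjj
        for k in range(p - 1):
            ik = k if k < j else k + 1
            K[ik, j] = -Beta[k, j] * kjj
    # symmetrize; an edge is absent exactly when either column's coefficient is 0
    for i in range(p):
        for j in range(i + 1, p):
            if K[i, j] == 0.0 or K[j, i] == 0.0:
                K[i, j] = 0.0
                K[j, i] = 0.0
            else:
                v = 0.5 * (K[i, j] + K[j, i])
                K[i, j] = v
                K[j, i] = v
    return K


@njit(cache=True)
def _dual_gap(S, K, lam):
    p = S.shape[0]
    gap = -float(p)
    pen = 0.0
    for i in range(p):
        for j in range(p):
            gap += S[i, j] * K[i, j]
            if i != j:
                pen += abs(K[i, j])
    return gap + lam * pen


@njit(cache=True)
def glasso_core(S, lam, tol, max_iter, W, Beta):
    """Run sweeps until the duality gap drops below tol.

    Returns (K, gap, n_sweeps).  W and Beta are mutated (warm start state).
    """
    inner_tol = max(tol * 0.01, 1e-14)
    gap = np.inf
    K = _assemble_K(W, Beta)
    for it in range(max_iter):
        _glasso_sweep(S, lam, W, Beta, inner_tol, 200)
        K = _assemble_K(W, Beta)
        gap = _dual_gap(S, K, lam)
        if abs(gap) < tol:
            return K, gap, it + 1
    return K, gap, max_iter
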