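"""Cross-sectional Gaussian graphical model estimation with EBIC model selection.

The per-wave pipeline is: listwise-complete cases at the wave → within-wave
mean-centring → Pearson correlation matrix → graphical lasso over a
logarithmic λ grid → Extended BIC selection → partial-correlation edge
matrix  w_ij = −K_ij/√(K_ii·K_jj).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glasso import glasso_core
from .panel import PanelDataset

__all__ = ["SampleMoments", "GGMFit", "center_within_wave", "graphical_lasso",
           "ebic_select", "partial_correlations", "fit_wave_ggm"]


class EstimationError(RuntimeError):
    """Raised when a network cannot be estimated from the data provided."""


class ConvergenceError(EstimationError):
    """Graphical lasso failed to reach the duality-gap tolerance."""

    def __init__(self, msg: str, gap: float):
        super().__init__(msg)
        self.gap = gap


@dataclass
class SampleMoments:
    """Sample correlation matrix with its effective (complete-case) sample size."""

    S: np.ndarray
    n: int
    labels: list[str]

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        if not np.allclose(np.diag(S), 1.0, atol=1e-8):
            raise ValueError("S must have unit diagonal (correlation matrix)")
        if np.linalg.eigvalsh(S)[0] < -1e-10:
            raise ValueError("S must be positive semi-definite")
        self.S = S


@dataclass
class GGMFit:
    """An EBIC-selected graphical-lasso fit."""

    K: np.ndarray                    # precision matrix
    W: np.ndarray                    # partial-correlation edge matrix, zero diagonal
    lambda_selected: float
    ebic_trace: list[tuple]          # (λ, edge count, log-likelihood, EBIC)
    gamma: float
    n: int
    labels: list[str] = field(default_factory=list)

    @property
    def edge_count(self) -> int:
        p = self.W.shape[0]
        iu = np.triu_indices(p, 1)
        return int(np.count_nonzero(self.W[iu]))

    def edge_list(self, display: bool = False, display_threshold: float = 0.1) -> pd.DataFrame:
        """Edge list (node_i, node_j, weight); `display` applies the |w| > 0.1
        plotting filter and must never be used for analysis matrices."""
        p = self.W.shape[0]
        rows = []
        for i in range(p):
            for j in range(i + 1, p):
                w = self.W[i, j]
                if w == 0.0:
                    continue
                if display and abs(w) <= display_threshold:
                    continue
                rows.append({"node_i": self.labels[i], "node_j": self.labels[j], "weight": w})
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_json(self, path) -> None:
        obj = {
            "labels": self.labels,
            "W": self.W.tolist(),
            "lambda": self.lambda_selected,
            "gamma": self.gamma,
            "n": self.n,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)


def partial_correlations(K: np.ndarray) -> np.ndarray:
    """w_ij = −K_ij/√(K_ii·K_jj), zero diagonal."""
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return W


def center_within_wave(panel: PanelDataset, wave: str) -> tuple[pd.DataFrame, SampleMoments]:
    """Mean-centre each symptom column over the wave's complete cases.

    Returns the centred score matrix (complete cases only) and the
    :class:`SampleMoments` built from its Pearson correlations.
    """
    complete = panel.complete_cases(wave)
    n, p = complete.shape
    if n < max(10, p + 1):
        raise EstimationError(
            f"wave {wave!r} has only {n} complete cases; at least {max(10, p + 1)} "
            "are required — collect more data or pool waves"
        )
    sds = complete.std(axis=0, ddof=1)
    zero_var = sds[sds == 0.0].index.tolist()
    if zero_var:
        raise EstimationError(f"zero-variance symptom column(s) at wave {wave!r}: {zero_var}")
    centred = complete - complete.mean(axis=0)
    S = np.corrcoef(centred.to_numpy(), rowvar=False)
    return centred, SampleMoments(S=S, n=n, labels=list(complete.columns))


def graphical_lasso(S: np.ndarray, lam: float, tol: float = 1e-4,
                    max_iter: int = 200) -> np.ndarray:
    """ℓ1-penalized precision estimate (off-diagonal penalty λ).

    At λ = 0 the estimate converges to the matrix inverse of S.  Raises
    :class:`ConvergenceError` carrying the final duality gap if `max_iter`
    sweeps do not reach `tol`.
    """
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    p = S.shape[0]
    W = S.copy()
    Beta = np.zeros((p - 1, p))
    K, gap, _ = glasso_core(np.ascontiguousarray(S), float(lam), float(tol), int(max_iter), W, Beta)
    if abs(gap) >= tol:
        raise ConvergenceError(
            f"graphical lasso did not converge in {max_iter} sweeps (duality gap {gap:.3e})", gap
        )
    return K


def ebic_select(moments: SampleMoments, gamma: float = 0.5, n_lambda: int = 100,
                lambda_min_ratio: float = 0.01, tol: float = 1e-4,
                max_iter: int = 200) -> GGMFit:
    """Fit the graphical lasso over a log λ grid and select by Extended BIC.

    EBIC(λ) = −2·L + E·log n + 4·γ·E·log p, with L = (n/2)(log det K − tr(S·K))
    and E the number of nonzero upper-triangle off-diagonal precision entries.
    The grid runs from λ_max = max off-diagonal |S| down to
    λ_max·lambda_min_ratio; ties favour the sparser (larger-λ) model.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if n_lambda < 2:
        raise ValueError("n_lambda must be at least 2")
    S = np.ascontiguousarray(moments.S)
    n, p = moments.n, S.shape[0]
    iu = np.triu_indices(p, 1)

    lam_max = float(np.max(np.abs(S[iu]))) if p > 1 else 0.0
    if lam_max <= 0.0:
        K = graphical_lasso(S, 0.0, tol=tol, max_iter=max_iter)
        L = 0.5 * n * (np.linalg.slogdet(K)[1] - np.sum(S * K))
        return GGMFit(K=K, W=partial_correlations(K), lambda_selected=0.0,
                      ebic_trace=[(0.0, 0, float(L), float(-2 * L))],
                      gamma=gamma, n=n, labels=list(moments.labels))

    grid = np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambda)
    # pin the top of the grid to λ_max exactly: logspace rounding can land one
    # ulp below it, letting the maximal edge enter with an ~1e-18 coefficient
    # and silently removing the empty model from the path
    grid[0] = lam_max
    W_work = S.copy()
    Beta = np.zeros((p - 1, p))
    trace: list[tuple] = []
    fits: list[np.ndarray | None] = []
    n_failed = 0
    for lam in grid:
        K, gap, _ = glasso_core(S, float(lam), float(tol), int(max_iter), W_work, Beta)
        if abs(gap) >= tol:
            n_failed += 1
            fits.append(None)
            trace.append((float(lam), -1, np.nan, np.inf))
            continue
        E = int(np.count_nonzero(K[iu]))
        L = 0.5 * n * (np.linalg.slogdet(K)[1] - np.sum(S * K))
        ebic = -2.0 * L + E * np.log(n) + 4.0 * gamma * E * np.log(p)
        fits.append(K)
        trace.append((float(lam), E, float(L), float(ebic)))
    if n_failed == len(grid):
        raise EstimationError(f"no λ on the grid converged; trace: {trace}")

    ebics = np.array([t[3] for t in trace])
    best = int(np.argmin(ebics))  # first occurrence = largest λ on the descending grid
    K = fits[best]
    return GGMFit(K=K, W=partial_correlations(K), lambda_selected=float(grid[best]),
                  ebic_trace=trace, gamma=gamma, n=n, labels=list(moments.labels))


def fit_wave_ggm(panel: PanelDataset, wave: str, gamma: float = 0.5,
                 **ebic_kwargs) -> GGMFit:
    """Convenience: centre the wave, build moments, and EBIC-select the GGM."""
    _, moments = center_within_wave(panel, wave)
    return ebic_select(moments, gamma=gamma, **ebic_kwargs)
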