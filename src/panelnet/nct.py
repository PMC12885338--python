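"""Permutation invariance tests between two cross-sectional networks.

Two global statistics, following the standard network-comparison permutation
scheme: the network-structure statistic M = max_ij |w_ij^A − w_ij^B| and the
global-strength statistic S = |Σ|w^A| − Σ|w^B|| (global strength = sum of
absolute upper-triangle edge weights).  Rows are pooled, reassigned to groups
of the original sizes, and both networks re-estimated per permutation;
p-values use the add-one estimator (1 + #{perm ≥ obs}) / (1 + n_perm).

The pooled rows are put into a canonical (lexicographic) order before the
permutation stream is drawn, so swapping the two group labels leaves the
p-values exactly unchanged.  Waves are treated as independent groups even
when participants overlap — the standard usage of this test on panel waves;
the report carries that caveat.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ggm import SampleMoments, ebic_select

__all__ = ["NCTResult", "nct", "bonferroni"]

DEPENDENCE_CAVEAT = (
    "groups permuted as independent samples; overlapping participants across "
    "waves violate exchangeability strictly and p-values are approximate"
)


@dataclass
class NCTResult:
    M_observed: float
    S_observed: float
    p_structure: float
    p_global: float
    n_permutations: int
    seed: int
    caveat: str = DEPENDENCE_CAVEAT

    def to_json(self, path=None) -> dict:
        obj = {
            "M_observed": self.M_observed,
            "S_observed": self.S_observed,
            "p_structure": self.p_structure,
            "p_global": self.p_global,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "caveat": self.caveat,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True)
        return obj


def _statistics(a: np.ndarray, b: np.ndarray, gamma: float, ebic_kwargs: dict) -> tuple[float, float]:
    iu = np.triu_indices(a.shape[1], 1)
    Ws = []
    for x in (a, b):
        S = np.corrcoef(x, rowvar=False)
        fit = ebic_select(SampleMoments(S=S, n=x.shape[0], labels=[str(i) for i in range(x.shape[1])]),
                          gamma=gamma, **ebic_kwargs)
        Ws.append(fit.W)
    M = float(np.max(np.abs(Ws[0] - Ws[1])))
    gs = [float(np.sum(np.abs(W[iu]))) for W in Ws]
    return M, abs(gs[0] - gs[1])


def nct(data_a, data_b, n_permutations: int = 1000, gamma: float = 0.5,
        seed: int = 0, **ebic_kwargs) -> NCTResult:
    """Network-structure and global-strength invariance tests.

    `data_a` / `data_b` are centred score matrices (rows = participants,
    same 9 columns).  Keyword arguments are forwarded to the EBIC-glasso
    estimator (e.g. ``n_lambda`` for coarser grids in simulations).
    """
    a = np.asarray(data_a, dtype=float)
    b = np.asarray(data_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("both groups must be 2-D with the same columns")
    p = a.shape[1]
    if min(a.shape[0], b.shape[0]) < p + 1:
        raise ValueError(f"each group needs at least {p + 1} rows")

    M_obs, S_obs = _statistics(a, b, gamma, ebic_kwargs)

    pooled = np.vstack([a, b])
    # canonical row order makes the permutation stream label-symmetric
    order = np.lexsort(pooled.T[::-1])
    pooled = pooled[order]
    # splitting at the smaller group size keeps the statistics label-symmetric
    # (both M and S are symmetric in the two groups)
    n_a = min(a.shape[0], b.shape[0])
    n_tot = pooled.shape[0]

    rng = np.random.default_rng(seed)
    ge_M = 0
    ge_S = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_tot)
        M_p, S_p = _statistics(pooled[perm[:n_a]], pooled[perm[n_a:]], gamma, ebic_kwargs)
        if M_p >= M_obs:
            ge_M += 1
        if S_p >= S_obs:
            ge_S += 1
    p_struct = (1 + ge_M) / (1 + n_permutations)
    p_glob = (1 + ge_S) / (1 + n_permutations)
    return NCTResult(M_observed=M_obs, S_observed=S_obs, p_structure=p_struct,
                     p_global=p_glob, n_permutations=n_permutations, seed=seed)


def bonferroni(p_values, m: int) -> list[float]:
    """p_adj = min(1, m·p); `m` must cover the whole family of tests."""
    p_values = list(p_values)
    if m < len(p_values):
        raise ValueError("m must be at least the number of p-values")
    return [min(1.0, m * float(p)) for p in p_values]
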