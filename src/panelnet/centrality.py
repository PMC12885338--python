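"""Weighted centrality indices for cross-sectional symptom networks.

Four node indices on an undirected weighted edge matrix W (zero diagonal):

* strength            s_i  = Σ_j |w_ij|
* expected influence  ei_i = Σ_j w_ij  (signed)
* closeness           c_i  = 1 / Σ_{j≠i} d(i,j)
* betweenness         b_i  = Σ_{s<t, s≠i≠t} σ_st(i)/σ_st

where d(i,j) is the shortest-path distance with edge length 1/|w_ij|
(negative edges enter by absolute value), σ_st counts shortest s–t paths and
σ_st(i) those passing through i.  Path-length ties are detected with a
relative tolerance of 1e−10.  Conventions for disconnected graphs: an
unreachable pair has d = ∞ and σ = 0; a node with any unreachable partner has
closeness 0; pairs with σ_st = 0 contribute 0 to betweenness.

Raw indices are z-scored across nodes (denominator N−1; constant columns map
to all-zero z) to match how centrality profiles are reported and compared.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ShortestPathTable", "CentralityTable", "strength", "expected_influence",
           "shortest_paths", "closeness", "betweenness", "standardize",
           "compute_centrality"]

#: relative tolerance for detecting equal-length shortest paths
TIE_RTOL = 1e-10

INDEX_NAMES = ["strength", "expected_influence", "closeness", "betweenness"]


def _check_W(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("W must be symmetric")
    if np.any(np.diag(W) != 0.0):
        raise ValueError("W must have a zero diagonal")
    return W


def strength(W: np.ndarray) -> np.ndarray:
    """Sum of absolute incident edge weights per node."""
    return np.abs(_check_W(W)).sum(axis=1)


def expected_influence(W: np.ndarray) -> np.ndarray:
    """Signed sum of incident edge weights per node."""
    return _check_W(W).sum(axis=1)


@dataclass
class ShortestPathTable:
    """All-pairs shortest-path distances and path counts."""

    d: np.ndarray       # pairwise distances, ∞ for unreachable pairs
    sigma: np.ndarray   # number of shortest paths per pair (0 if unreachable)

    def sigma_through(self, i: int) -> np.ndarray:
        """σ_st(i): shortest s–t paths passing through interior node i."""
        n = self.d.shape[0]
        out = np.zeros((n, n))
        for s in range(n):
            if s == i:
                continue
            for t in range(n):
                if t == i or t == s:
                    continue
                via = self.d[s, i] + self.d[i, t]
                if np.isfinite(via) and np.isclose(via, self.d[s, t], rtol=TIE_RTOL, atol=0.0):
                    out[s, t] = self.sigma[s, i] * self.sigma[i, t]
        return out


def shortest_paths(W: np.ndarray) -> ShortestPathTable:
    """Dijkstra over edge lengths 1/|w| with exact shortest-path counting."""
    W = _check_W(W)
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        length = np.where(W != 0.0, 1.0 / np.abs(W), np.inf)
    d = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist = np.full(n, np.inf)
        cnt = np.zeros(n)
        dist[s] = 0.0
        cnt[s] = 1.0
        done = np.zeros(n, dtype=bool)
        heap = [(0.0, s)]
        while heap:
            du, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            for v in range(n):
                luv = length[u, v]
                if not np.isfinite(luv) or done[v]:
                    continue
                alt = du + luv
                if alt < dist[v] and not np.isclose(alt, dist[v], rtol=TIE_RTOL, atol=0.0):
                    dist[v] = alt
                    cnt[v] = cnt[u]
                    heapq.heappush(heap, (alt, v))
                elif np.isclose(alt, dist[v], rtol=TIE_RTOL, atol=0.0):
                    cnt[v] += cnt[u]
        d[s] = dist
        sigma[s] = cnt
        sigma[s, s] = 1.0
    d[np.arange(n), np.arange(n)] = 0.0
    sigma[~np.isfinite(d)] = 0.0
    return ShortestPathTable(d=d, sigma=sigma)


def closeness(paths: ShortestPathTable) -> np.ndarray:
    """1 / Σ_{j≠i} d(i,j); 0 when any partner is unreachable (or N = 1)."""
    d = paths.d
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        others = np.delete(d[i], i)
        if others.size == 0 or not np.all(np.isfinite(others)):
            continue
        total = float(others.sum())
        out[i] = 1.0 / total if total > 0 else 0.0
    return out


def betweenness(paths: ShortestPathTable) -> np.ndarray:
    """Σ over unordered pairs {s,t}, s≠t≠i, of σ_st(i)/σ_st."""
    d, sigma = paths.d, paths.sigma
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        through = paths.sigma_through(i)
        for s in range(n):
            if s == i:
                continue
            for t in range(s + 1, n):
                if t == i or sigma[s, t] == 0.0:
                    continue
                out[i] += through[s, t] / sigma[s, t]
    return out


@dataclass
class CentralityTable:
    """Raw and z-scored centrality indices, one row per node."""

    table: pd.DataFrame  # columns: index names and their *_z twins
    N: int

    def to_long(self, wave: str | None = None) -> pd.DataFrame:
        rows = []
        for node in self.table.index:
            for name in INDEX_NAMES:
                rows.append({
                    "node": node, "index": name,
                    "raw": self.table.loc[node, name],
                    "z": self.table.loc[node, f"{name}_z"],
                    "wave": wave,
                })
        return pd.DataFrame(rows)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def standardize(table: CentralityTable) -> CentralityTable:
    """Recompute z columns; z = (raw − mean)/sd with denominator N−1."""
    if table.N < 2:
        raise ValueError("standardization requires at least 2 nodes")
    out = table.table.copy()
    for name in INDEX_NAMES:
        out[f"{name}_z"] = _zscore(out[name].to_numpy())
    return CentralityTable(table=out, N=table.N)


def compute_centrality(W: np.ndarray, labels: list[str] | None = None) -> CentralityTable:
    """All four indices (raw and z-scored) for an undirected edge matrix."""
    W = _check_W(W)
    n = W.shape[0]
    labels = labels if labels is not None else [f"V{i}" for i in range(n)]
    paths = shortest_paths(W)
    raw = {
        "strength": strength(W),
        "expected_influence": expected_influence(W),
        "closeness": closeness(paths),
        "betweenness": betweenness(paths),
    }
    frame = pd.DataFrame(raw, index=labels)
    table = CentralityTable(table=frame, N=n)
    for name in INDEX_NAMES:
        frame[f"{name}_z"] = _zscore(frame[name].to_numpy())
    return table
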