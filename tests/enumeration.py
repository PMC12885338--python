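"""Independent brute-force shortest-path oracle used by the centrality tests.

Enumerates every simple path between every node pair (feasible for networks
of up to ~7 nodes), computing path lengths as sums of 1/|w| along the path.
Kept deliberately free of any code from the package under test.
"""

from itertools import permutations

import numpy as np

TOL = 1e-9


def all_simple_paths(W, s, t):
    n = W.shape[0]
    others = [v for v in range(n) if v not in (s, t)]
    paths = []
    for r in range(len(others) + 1):
        for mid in permutations(others, r):
            nodes = (s, *mid, t)
            if all(W[nodes[k], nodes[k + 1]] != 0 for k in range(len(nodes) - 1)):
                paths.append(nodes)
    return paths


def path_length(W, nodes):
    return sum(1.0 / abs(W[nodes[k], nodes[k + 1]]) for k in range(len(nodes) - 1))


def brute_shortest(W):
    """(distance matrix, list-of-shortest-paths matrix) by full enumeration."""
    n = W.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    shortest = [[[] for _ in range(n)] for _ in range(n)]
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = all_simple_paths(W, s, t)
            if not paths:
                continue
            lengths = [path_length(W, p) for p in paths]
            best = min(lengths)
            d[s, t] = best
            shortest[s][t] = [p for p, L in zip(paths, lengths)
                              if L <= best * (1 + TOL)]
    return d, shortest


def brute_closeness(W):
    d, _ = brute_shortest(W)
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        others = np.delete(d[i], i)
        if others.size and np.all(np.isfinite(others)) and others.sum() > 0:
            out[i] = 1.0 / others.sum()
    return out


def brute_betweenness(W):
    d, shortest = brute_shortest(W)
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if i in (s, t) or not shortest[s][t]:
                    continue
                sigma = len(shortest[s][t])
                through = sum(1 for p in shortest[s][t] if i in p[1:-1])
                out[i] += through / sigma
    return out
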