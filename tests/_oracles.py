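"""Brute-force oracles shared across test modules: exhaustive shortest-path
enumeration for distance/betweenness checks, and a random weighted-graph
generator."""

import itertools

import numpy as np


def random_weights(p, seed, density=0.7):
    rng = np.random.default_rng(seed)
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(-0.5, 0.5)
    return W


def _path_length(W, path):
    length = 0.0
    for a, b in zip(path, path[1:]):
        if W[a, b] == 0:
            return None
        length += 1.0 / abs(W[a, b])
    return length


def enumerate_distances(W):
    """Shortest 1/|w| path distances by exhaustive path enumeration."""
    p = W.shape[0]
    D = np.full((p, p), np.inf)
    np.fill_diagonal(D, 0.0)
    for s, t in itertools.combinations(range(p), 2):
        best = np.inf
        for k in range(0, p - 1):
            for mid in itertools.permutations(set(range(p)) - {s, t}, k):
                length = _path_length(W, (s,) + mid + (t,))
                if length is not None:
                    best = min(best, length)
        D[s, t] = D[t, s] = best
    return D


def enumerate_betweenness(W):
    """Fractional-credit betweenness from explicit shortest-path lists."""
    p = W.shape[0]
    D = enumerate_distances(W)
    bc = np.zeros(p)
    for s, t in itertools.combinations(range(p), 2):
        if not np.isfinite(D[s, t]):
            continue
        shortest = []
        for k in range(0, p - 1):
            for mid in itertools.permutations(set(range(p)) - {s, t}, k):
                path = (s,) + mid + (t,)
                length = _path_length(W, path)
                if length is not None and np.isclose(
                    length, D[s, t], rtol=1e-12, atol=1e-12
                ):
                    shortest.append(path)
        for path in shortest:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc
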