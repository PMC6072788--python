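"""Independent brute-force oracles for the graph measures.

Deliberately naive: distances enumerate every simple path, triangles use a
triple loop, and the global measures evaluate their defining sums term by
term.  Only usable on tiny graphs; the tests compare the package's vectorized
implementations against these.
"""

import itertools

import numpy as np


def brute_distances(M, weighted):
    """All-pairs shortest paths by enumerating every simple path."""
    n = M.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            others = [v for v in range(n) if v not in (s, t)]
            best = np.inf
            for k in range(len(others) + 1):
                for mid in itertools.permutations(others, k):
                    path = (s, *mid, t)
                    cost = 0.0
                    ok = True
                    for u, v in zip(path, path[1:]):
                        if M[u, v] <= 0:
                            ok = False
                            break
                        cost += 1.0 / M[u, v] if weighted else 1.0
                    if ok and cost < best:
                        best = cost
            D[s, t] = best
    return D


def brute_triangles_degrees(M, weighted):
    n = M.shape[0]
    t = np.zeros(n)
    k = np.zeros(n)
    for i in range(n):
        k[i] = sum(1 for j in range(n) if j != i and M[i, j] > 0)
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if len({i, j, h}) < 3:
                    continue
                if weighted:
                    acc += (M[i, j] * M[i, h] * M[j, h]) ** (1.0 / 3.0)
                else:
                    acc += 1.0 if (M[i, j] and M[i, h] and M[j, h]) else 0.0
        t[i] = acc / 2.0
    return t, k


def brute_path_length(M, weighted):
    """Characteristic path length; None when some pair is unreachable."""
    D = brute_distances(M, weighted)
    n = M.shape[0]
    total = 0.0
    for i in range(n):
        inner = 0.0
        for j in range(n):
            if j == i:
                continue
            if np.isinf(D[i, j]):
                return None
            inner += D[i, j]
        total += inner / (n - 1)
    return total / n


def brute_efficiency(M, weighted):
    D = brute_distances(M, weighted)
    n = M.shape[0]
    total = 0.0
    for i in range(n):
        inner = 0.0
        for j in range(n):
            if j != i and not np.isinf(D[i, j]):
                inner += 1.0 / D[i, j]
        total += inner / (n - 1)
    return total / n


def brute_clustering(M, weighted):
    t, k = brute_triangles_degrees(M, weighted)
    n = M.shape[0]
    total = 0.0
    for i in range(n):
        if k[i] >= 2:
            total += 2.0 * t[i] / (k[i] * (k[i] - 1))
    return total / n


def brute_transitivity(M, weighted):
    """Transitivity; None when no node has degree >= 2."""
    t, k = brute_triangles_degrees(M, weighted)
    denom = float(sum(ki * (ki - 1) for ki in k))
    if denom == 0:
        return None
    return 2.0 * float(t.sum()) / denom


def brute_mns(sizes, means, reference, tolerance):
    """Permanence-rule MNS by explicitly checking every candidate size."""
    pairs = sorted(zip(sizes, means))
    for idx, (s, _) in enumerate(pairs):
        if all(
            abs(m - reference) <= tolerance * abs(reference)
            for _, m in pairs[idx:]
        ):
            return s
    return None
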