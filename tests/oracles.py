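"""Independent brute-force oracles used by the tests.

Everything here is written as plain triple loops over dictionaries so
it shares no code path (and no vectorization choices) with the package
implementation it checks.
"""

import math

import numpy as np


def naive_frequencies(matrix):
    """f1, f2, q by literal counting (full-S denominator convention)."""
    matrix = np.asarray(matrix)
    S, L = matrix.shape
    f1 = [[0.0] * 20 for _ in range(L)]
    for i in range(L):
        for s in range(S):
            a = matrix[s, i]
            if a > 0:
                f1[i][a - 1] += 1.0 / S
    f2 = {}
    for i in range(L):
        for j in range(L):
            for a in range(1, 21):
                for b in range(1, 21):
                    n = 0
                    for s in range(S):
                        if matrix[s, i] == a and matrix[s, j] == b:
                            n += 1
                    f2[(i, a - 1, j, b - 1)] = n / S
    total = 0
    pooled = [0.0] * 20
    for s in range(S):
        for i in range(L):
            a = matrix[s, i]
            if a > 0:
                pooled[a - 1] += 1
                total += 1
    q = [c / total for c in pooled]
    return f1, f2, q


def naive_coupling(matrix):
    """Weighted position-coupling matrix by the step-by-step recipe:
    covariance, log-odds conservation weight with 1/(2S) clamping,
    Frobenius reduction over amino acids, zero diagonal."""
    matrix = np.asarray(matrix)
    S, L = matrix.shape
    f1, f2, q = naive_frequencies(matrix)
    eps = 1.0 / (2 * S)

    def clamp(x):
        return min(max(x, eps), 1.0 - eps)

    phi = [[0.0] * 20 for _ in range(L)]
    for i in range(L):
        for a in range(20):
            f = clamp(f1[i][a])
            qa = clamp(q[a])
            phi[i][a] = math.log(f * (1.0 - qa) / ((1.0 - f) * qa))

    W = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            total = 0.0
            for a in range(20):
                for b in range(20):
                    c = f2[(i, a, j, b)] - f1[i][a] * f1[j][b]
                    total += (phi[i][a] * phi[j][b] * c) ** 2
            W[i, j] = math.sqrt(total)
    return W


def varimax_grid_best(V, step_deg=0.1):
    """Best varimax criterion over an exhaustive planar-rotation grid
    (valid for exactly two factors)."""
    assert V.shape[1] == 2
    best = -np.inf
    for ang in np.deg2rad(np.arange(0.0, 90.0, step_deg)):
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        B2 = (V @ R) ** 2
        crit = float(np.sum((B2 ** 2).mean(axis=0) - B2.mean(axis=0) ** 2))
        best = max(best, crit)
    return best


def jaccard(a, b):
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


def best_jaccard(reference, predicted_lists):
    return max((jaccard(reference, p) for p in predicted_lists), default=0.0)
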