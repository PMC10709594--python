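"""Shared brute-force oracles used by more than one test module."""

import numpy as np


def periodic_operator_matrix(n0, n1, dx, a, p):
    """Explicit finite-difference matrix of (id - a^2 Lap)^p, periodic grid."""
    N = n0 * n1
    lap = np.zeros((N, N))
    for i in range(n0):
        for j in range(n1):
            k = i * n1 + j
            lap[k, k] = -4.0 / dx**2
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                lap[k, ((i + di) % n0) * n1 + (j + dj) % n1] += 1.0 / dx**2
    A = np.eye(N) - a * a * lap
    return np.linalg.matrix_power(A, int(p))
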