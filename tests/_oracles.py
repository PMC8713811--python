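"""Independent brute-force references used by the tests.

These deliberately re-derive results with the most naive correct algorithm
available (dynamic programming spelled out longhand, exhaustive enumeration)
so they share no code with the implementation they check.
"""

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = -1e9


def gotoh_global_score(a: str, b: str, open_gap: float = 10.0, extend_gap: float = 1.0) -> float:
    """Affine-gap global alignment score by explicit three-matrix DP."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_gap - extend_gap * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -open_gap - extend_gap * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(M[i - 1, j] - open_gap, X[i - 1, j] - extend_gap,
                          Y[i - 1, j] - open_gap)
            Y[i, j] = max(M[i, j - 1] - open_gap, Y[i, j - 1] - extend_gap,
                          X[i, j - 1] - open_gap)
    return float(max(M[n, m], X[n, m], Y[n, m]))
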