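"""Independent brute-force oracles used by the test suite.

These are deliberately separate implementations from the package code:
plain dynamic programming and sliding-window scans, written for clarity
rather than speed, against which the production paths are checked.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_global_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 16.0,
    gap_extend: float = 4.0,
) -> float:
    """Affine-gap global alignment score; a gap of length L costs
    open + L*extend, and end gaps are charged like internal gaps."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open - gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open - gap_extend,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def smith_waterman_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Best local alignment score under the same affine-gap convention."""
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = max(0.0, diag + s)
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend, Y[i][j - 1] - gap_extend
            )
            best = max(best, M[i][j])
    return best


def hamming_hits(text: str, pattern: str, max_mismatch: int) -> list[int]:
    """Start offsets where pattern occurs with <= max_mismatch substitutions."""
    out = []
    m = len(pattern)
    for i in range(len(text) - m + 1):
        mism = sum(1 for x, y in zip(text[i : i + m], pattern) if x != y)
        if mism <= max_mismatch:
            out.append(i)
    return out
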