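"""Independent brute-force oracles used by the test suite.

The alignment oracle is a plain full-matrix dynamic program over tuple
values — no rolling rows, no vectorization, no shared code with the
package kernel — implementing the same objective: free terminal gaps,
affine internal gaps costing gap_open + L*gap_extend, at least one aligned
column, and lexicographic preference (score, matches, fewer columns).
"""

from __future__ import annotations

MINF = (-(10**9), 0, 0)


def semiglobal_oracle(a: str, b: str, scoring=(2, -3, -5, -2)):
    """Return (score, matches, aligned_columns) of the optimal overlap alignment."""
    match, mismatch, gap_open, gap_extend = scoring
    go = gap_open + gap_extend  # first gap column
    ge = gap_extend
    m, n = len(a), len(b)
    M = [[MINF] * (n + 1) for _ in range(m + 1)]
    X = [[MINF] * (n + 1) for _ in range(m + 1)]
    Y = [[MINF] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        M[i][0] = (0, 0, 0)
    for j in range(n + 1):
        M[0][j] = (0, 0, 0)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            ok = a[i - 1] == b[j - 1] and a[i - 1] in "ACGT"
            s = match if ok else mismatch
            M[i][j] = (prev[0] + s, prev[1] + (1 if ok else 0), prev[2] - 1)
            X[i][j] = max(
                (M[i - 1][j][0] + go, M[i - 1][j][1], M[i - 1][j][2] - 1),
                (X[i - 1][j][0] + ge, X[i - 1][j][1], X[i - 1][j][2] - 1),
            )
            Y[i][j] = max(
                (M[i][j - 1][0] + go, M[i][j - 1][1], M[i][j - 1][2] - 1),
                (Y[i][j - 1][0] + ge, Y[i][j - 1][1], Y[i][j - 1][2] - 1),
            )
    ends = [M[m][j] for j in range(1, n + 1)] + [M[i][n] for i in range(1, m + 1)]
    score, matches, negcols = max(ends)
    return score, matches, -negcols


def random_seq(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
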