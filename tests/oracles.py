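"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import math

NEG = -(10**9)


def sw_oracle(query: str, ref: str, match=2, mismatch=-2, gap_open=-5, gap_extend=-1):
    """Plain-dict Gotoh local alignment, written independently of the
    package's kernel.

    Returns (score, query_start, query_end, ref_start, ref_end) with ties
    broken by the smallest (query_start, ref_start, query_end, ref_end).
    A gap of length k costs gap_open + (k-1)*gap_extend (both negative).
    """
    m, n = len(query), len(ref)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    # start[i][j]: origin cell of the best local path ending at (i, j), per state
    SH = [[None] * (n + 1) for _ in range(m + 1)]
    SE = [[None] * (n + 1) for _ in range(m + 1)]
    SF = [[None] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cands_e = [
                (H[i][j - 1] + gap_open, SH[i][j - 1]),
                (E[i][j - 1] + gap_extend, SE[i][j - 1]),
            ]
            E[i][j], SE[i][j] = max(cands_e, key=lambda t: (t[0], _neg(t[1])))
            cands_f = [
                (H[i - 1][j] + gap_open, SH[i - 1][j]),
                (F[i - 1][j] + gap_extend, SF[i - 1][j]),
            ]
            F[i][j], SF[i][j] = max(cands_f, key=lambda t: (t[0], _neg(t[1])))
            s = match if query[i - 1] == ref[j - 1] else mismatch
            diag_start = SH[i - 1][j - 1] if H[i - 1][j - 1] > 0 else (i - 1, j - 1)
            cands_h = [
                (H[i - 1][j - 1] + s, diag_start),
                (E[i][j], SE[i][j]),
                (F[i][j], SF[i][j]),
                (0, None),
            ]
            H[i][j], SH[i][j] = max(cands_h, key=lambda t: (t[0], _neg(t[1])))
    best = max(max(row) for row in H)
    if best <= 0:
        return 0, 0, 0, 0, 0
    hits = []
    for i in range(m + 1):
        for j in range(n + 1):
            if H[i][j] == best and SH[i][j] is not None:
                qs, rs = SH[i][j]
                hits.append((qs, rs, i, j))
    qs, rs, qe, re = min(hits)
    return best, qs, qe, rs, re


def _neg(start):
    # prefer the lexicographically smallest start on score ties
    return (-start[0], -start[1]) if start is not None else (-(10**9), -(10**9))


def poisson_upper_tail(n: int, lam: float) -> float:
    """P(X >= n) by direct partial summation of the Poisson pmf."""
    acc = 0.0
    term = math.exp(-lam)
    for k in range(n):
        acc += term
        term = term * lam / (k + 1) if lam > 0 else 0.0
    return max(0.0, 1.0 - acc)
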