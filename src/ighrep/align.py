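"""Local (Smith-Waterman) nucleotide alignment.

Reads are mapped to germline V/D/J/C segments with an affine-gap local
aligner (Gotoh recurrences). The dynamic-programming fill runs through a
numba-jitted kernel; traceback and tie-breaking are done in Python on the
returned matrices. Ties between equally scoring alignments are broken by
the earliest query start, then the earliest reference start, so calls are
reproducible across runs and platforms.

Scoring convention: a gap run of length k costs ``-(gap_open + (k-1) *
gap_extend)`` with both penalties given as negative numbers, i.e. the
opening base pays ``gap_open`` and each extension base ``gap_extend``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

NEG_INF = np.int32(-(10**8))

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


@dataclass(frozen=True)
class Scoring:
    """Nucleotide scoring scheme (defaults: +2/-2, gap open -5, extend -1)."""

    match: int = 2
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -1


@dataclass
class AlignmentHit:
    """One local alignment of a query against a reference segment.

    Coordinates are 0-based, half-open. ``cigar`` is a run-length edit
    string over the ops ``=`` (match), ``X`` (mismatch), ``I`` (query base
    absent from reference) and ``D`` (reference base absent from query).
    """

    segment_id: str | None
    score: int
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    n_match: int
    n_mismatch: int
    n_gap: int
    cigar: str
    query_offset: int = field(default=0, repr=False)

    def shifted(self, offset: int) -> "AlignmentHit":
        """Return a copy with query coordinates shifted by ``offset``.

        Used when a segment was aligned against a sub-window of the read.
        """
        return replace(
            self,
            query_start=self.query_start + offset,
            query_end=self.query_end + offset,
            query_offset=self.query_offset + offset,
        )

    def columns(self):
        """Yield (op, query_pos, ref_pos) per alignment column."""
        q, r = self.query_start, self.ref_start
        for n, op in re.findall(r"(\d+)([=XID])", self.cigar):
            for _ in range(int(n)):
                yield op, q, r
                if op in "=XI":
                    q += 1
                if op in "=XD":
                    r += 1


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_SENTINEL = np.int32(2**30)


@njit(cache=True)
def _fill(q, r, match, mismatch, gap_open, gap_extend):
    """Gotoh fill with origin propagation.

    Besides the three score matrices, each state carries the
    lexicographically smallest (query_start, ref_start) — encoded as
    ``qs * (n + 2) + rs`` — over all optimal paths reaching the cell, so
    the stated tie-break is exact rather than traceback-dependent.
    """
    m, n = q.shape[0], r.shape[0]
    stride = np.int32(n + 2)
    # interior cells are all written below; only boundaries need init
    H = np.empty((m + 1, n + 1), dtype=np.int32)
    E = np.empty((m + 1, n + 1), dtype=np.int32)  # gap in query
    F = np.empty((m + 1, n + 1), dtype=np.int32)  # gap in ref
    OH = np.empty((m + 1, n + 1), dtype=np.int32)
    OE = np.empty((m + 1, n + 1), dtype=np.int32)
    OF = np.empty((m + 1, n + 1), dtype=np.int32)
    for j in range(n + 1):
        H[0, j] = 0
        E[0, j] = NEG_INF
        F[0, j] = NEG_INF
        OH[0, j] = _SENTINEL
        OE[0, j] = _SENTINEL
        OF[0, j] = _SENTINEL
    for i in range(m + 1):
        H[i, 0] = 0
        E[i, 0] = NEG_INF
        F[i, 0] = NEG_INF
        OH[i, 0] = _SENTINEL
        OE[i, 0] = _SENTINEL
        OF[i, 0] = _SENTINEL
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = E[i, j - 1] + gap_extend
            eo = OE[i, j - 1]
            ho = H[i, j - 1] + gap_open
            hoo = OH[i, j - 1]
            if ho > e or (ho == e and hoo < eo):
                E[i, j] = ho
                OE[i, j] = hoo
            else:
                E[i, j] = e
                OE[i, j] = eo
            f = F[i - 1, j] + gap_extend
            fo = OF[i - 1, j]
            vo = H[i - 1, j] + gap_open
            voo = OH[i - 1, j]
            if vo > f or (vo == f and voo < fo):
                F[i, j] = vo
                OF[i, j] = voo
            else:
                F[i, j] = f
                OF[i, j] = fo
            s = match if qi == r[j - 1] and qi < 4 else mismatch
            d = H[i - 1, j - 1] + s
            if H[i - 1, j - 1] > 0:
                do = OH[i - 1, j - 1]
            else:
                do = np.int32(i - 1) * stride + np.int32(j - 1)
            best = d
            besto = do
            if E[i, j] > best or (E[i, j] == best and OE[i, j] < besto):
                best = E[i, j]
                besto = OE[i, j]
            if F[i, j] > best or (F[i, j] == best and OF[i, j] < besto):
                best = F[i, j]
                besto = OF[i, j]
            if best <= 0:
                H[i, j] = 0
                OH[i, j] = _SENTINEL
            else:
                H[i, j] = best
                OH[i, j] = besto
    return H, E, F, OH, OE, OF


@njit(cache=True)
def _fill_score(q, r, match, mismatch, gap_open, gap_extend):
    """Scores-only Gotoh fill (rolling rows); returns the max local score.

    ~6x faster than :func:`_fill`; used to rank candidate segments before
    the full kernel computes boundaries and the edit string for the winner.
    """
    m, n = q.shape[0], r.shape[0]
    Hp = np.zeros(n + 1, dtype=np.int32)
    Hc = np.zeros(n + 1, dtype=np.int32)
    Ep = np.full(n + 1, NEG_INF, dtype=np.int32)
    Ec = np.full(n + 1, NEG_INF, dtype=np.int32)
    Fp = np.full(n + 1, NEG_INF, dtype=np.int32)
    Fc = np.full(n + 1, NEG_INF, dtype=np.int32)
    best = np.int32(0)
    for i in range(1, m + 1):
        qi = q[i - 1]
        Hc[0] = 0
        Ec[0] = NEG_INF
        Fc[0] = NEG_INF
        for j in range(1, n + 1):
            e = Ec[j - 1] + gap_extend
            ho = Hc[j - 1] + gap_open
            Ec[j] = e if e > ho else ho
            f = Fp[j] + gap_extend
            vo = Hp[j] + gap_open
            Fc[j] = f if f > vo else vo
            s = match if qi == r[j - 1] and qi < 4 else mismatch
            h = Hp[j - 1] + s
            if Ec[j] > h:
                h = Ec[j]
            if Fc[j] > h:
                h = Fc[j]
            if h < 0:
                h = 0
            Hc[j] = h
            if h > best:
                best = h
        Hp, Hc = Hc, Hp
        Ep, Ec = Ec, Ep
        Fp, Fc = Fc, Fp
    return best


def sw_score(query: str, ref: str, scoring: Scoring = Scoring()) -> int:
    """Max local alignment score only (no boundaries, no edit string).

    Exactly equals ``smith_waterman(query, ref, scoring).score``.
    """
    if not query or not ref:
        raise ValueError("sw_score requires non-empty sequences")
    return int(
        _fill_score(
            encode(query), encode(ref),
            np.int32(scoring.match), np.int32(scoring.mismatch),
            np.int32(scoring.gap_open), np.int32(scoring.gap_extend),
        )
    )


def _traceback(H, E, F, OH, OE, OF, q, r, i, j, stride, sc: Scoring):
    """Walk the optimal path with the cell's recorded origin back from (i, j)."""
    ops: list[str] = []
    state = "M"
    origin = OH[i, j]
    while True:
        if state == "M":
            if H[i, j] == 0:
                break
            s = sc.match if (q[i - 1] == r[j - 1] and q[i - 1] < 4) else sc.mismatch
            if H[i - 1, j - 1] > 0:
                diag_o = OH[i - 1, j - 1]
            else:
                diag_o = (i - 1) * stride + (j - 1)
            if H[i, j] == H[i - 1, j - 1] + s and diag_o == origin:
                ops.append("=" if s == sc.match else "X")
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j] and OE[i, j] == origin:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            if E[i, j] == H[i, j - 1] + sc.gap_open and OH[i, j - 1] == origin:
                state = "M"
            j -= 1
        else:
            ops.append("I")
            if F[i, j] == H[i - 1, j] + sc.gap_open and OH[i - 1, j] == origin:
                state = "M"
            i -= 1
    return ops[::-1], i, j


def _rle(ops: list[str]) -> str:
    out = []
    k = 0
    while k < len(ops):
        j = k
        while j < len(ops) and ops[j] == ops[k]:
            j += 1
        out.append(f"{j - k}{ops[k]}")
        k = j
    return "".join(out)


def smith_waterman(
    query: str,
    ref: str,
    scoring: Scoring = Scoring(),
    segment_id: str | None = None,
) -> AlignmentHit:
    """Best local alignment of ``query`` against ``ref``.

    Among equally scoring alignments the one with the smallest
    ``(query_start, ref_start, query_end, ref_end)`` is returned.
    """
    if not query or not ref:
        raise ValueError("smith_waterman requires non-empty sequences")
    q, r = encode(query), encode(ref)
    H, E, F, OH, OE, OF = _fill(
        q, r,
        np.int32(scoring.match), np.int32(scoring.mismatch),
        np.int32(scoring.gap_open), np.int32(scoring.gap_extend),
    )
    best = int(H.max())
    if best <= 0:
        return AlignmentHit(segment_id, 0, 0, 0, 0, 0, 0, 0, 0, "")
    ends = np.argwhere(H == best)
    # minimal (origin, end) over all optimal alignments
    keys = [(int(OH[i, j]), int(i), int(j)) for i, j in ends]
    _, i_end, j_end = min(keys)
    stride = len(ref) + 2
    ops, qs, rs = _traceback(
        H, E, F, OH, OE, OF, q, r, i_end, j_end, stride, scoring
    )
    qe, re_ = i_end, j_end
    n_match = ops.count("=")
    n_mm = ops.count("X")
    n_gap = ops.count("I") + ops.count("D")
    return AlignmentHit(
        segment_id, best, qs, qe, rs, re_, n_match, n_mm, n_gap, _rle(ops)
    )


def score_from_cigar(cigar: str, scoring: Scoring = Scoring()) -> int:
    """Recompute an alignment score from its edit string (invariant check)."""
    total = 0
    for n, op in re.findall(r"(\d+)([=XID])", cigar):
        n = int(n)
        if op == "=":
            total += n * scoring.match
        elif op == "X":
            total += n * scoring.mismatch
        else:
            total += scoring.gap_open + (n - 1) * scoring.gap_extend
    return total
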