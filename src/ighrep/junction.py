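"""Canonical decomposition of the V(D)J junction.

The nucleotides between the last germline-V base and the first germline-J
base of a rearrangement are a mixture of surviving D template, palindromic
(P) additions and nontemplated (N) additions. That partition is not unique
— an N base that happens to equal the next germline base is
indistinguishable from template — so the package fixes one deterministic
convention, used identically for simulated ground truth and for annotation:

* template first: germline V and J matches are extended maximally before
  anything is labeled N (callers pass boundaries that already reflect this);
* P additions are recognized only on untrimmed ends, as up-to-2-nt
  reverse-complement mirrors of the adjacent segment terminus;
* the D segment is the catalog entry with the longest exact run (>= a
  configurable minimum, default 5 nt) inside the remaining gap; below the
  minimum no D is called and the bases count as a single N stretch;
* remaining bases are N: ``n2`` at the V-DJ join, ``n1`` at the D-J join.

This convention biases N counts low (ambiguous bases go to template), which
is the conservative choice for N-insertion profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dna import longest_common_substring, revcomp


@dataclass
class JunctionDecomposition:
    d_id: str | None
    d5_del: int
    d3_del: int
    p2: str  # palindromic addition after the V end
    n2: str  # nontemplated bases at the V-DJ join
    n1: str  # nontemplated bases at the D-J join
    p1: str  # palindromic addition before the J start

    @property
    def n1_len(self) -> int:
        return len(self.n1)

    @property
    def n2_len(self) -> int:
        return len(self.n2)

    @property
    def n_total(self) -> int:
        return len(self.n1) + len(self.n2)


def _p_addition(gap_end: str, segment_end: str, p_max: int) -> str:
    """Longest <=p_max prefix of ``gap_end`` mirroring ``segment_end``."""
    for k in range(min(p_max, len(gap_end), len(segment_end)), 0, -1):
        if gap_end[:k] == revcomp(segment_end[-k:]):
            return gap_end[:k]
    return ""


def decompose_gap(
    gap: str,
    v_seq: str,
    v_del: int,
    j_seq: str,
    j_del: int,
    d_segments,
    d_min_match: int = 5,
    p_max: int = 2,
) -> JunctionDecomposition:
    """Partition the inter-template gap into P / N / D components.

    ``v_del`` and ``j_del`` are the observed (template-first) deletion
    counts; P additions can only exist on ends with zero deletion, because
    trimming removes the hairpin-derived bases.
    """
    p2 = _p_addition(gap, v_seq, p_max) if v_del == 0 else ""
    rest = gap[len(p2) :]

    d_id = None
    d5_del = d3_del = 0
    d_start = d_run = 0
    for d in d_segments:
        run, s_gap, s_d = longest_common_substring(rest, d.sequence)
        if run > d_run:
            d_id, d_run, d_start = d.id, run, s_gap
            d5_del, d3_del = s_d, len(d.sequence) - (s_d + run)
    if d_run < d_min_match:
        d_id = None

    if d_id is None:
        tail = rest
        n2 = ""
    else:
        n2 = rest[:d_start]
        tail = rest[d_start + d_run :]

    p1 = ""
    if j_del == 0 and tail:
        for k in range(min(p_max, len(tail), len(j_seq)), 0, -1):
            if tail[-k:] == revcomp(j_seq[:k]):
                p1 = tail[-k:]
                break
    n1 = tail[: len(tail) - len(p1)]

    if d_id is None:
        return JunctionDecomposition(None, 0, 0, p2, "", n1, p1)
    return JunctionDecomposition(d_id, d5_del, d3_del, p2, n2, n1, p1)
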