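"""Small nucleotide-string helpers shared across the pipeline."""

from __future__ import annotations

from Bio.Seq import Seq

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC codes used by the AID hotspot motifs.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "D": "AGT", "Y": "CT", "W": "AT", "R": "AG", "H": "TCA", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate a nucleotide string (standard nuclear code, frame 0)."""
    if len(nt) % 3:
        raise ValueError("sequence length not a multiple of 3")
    return str(Seq(nt).translate())


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def matches_iupac(seq: str, pattern: str) -> bool:
    """Exact-length match of ``seq`` against an IUPAC degenerate pattern."""
    if len(seq) != len(pattern):
        return False
    return all(s in IUPAC[p] for s, p in zip(seq, pattern))


def hotspot_class(seq: str, pos: int) -> str:
    """Classify position ``pos`` of a germline sequence by AID hotspot context.

    A position belongs to a hotspot if any 4-mer window covering it matches
    DGYW (D = A/G/T, Y = C/T, W = A/T) or, failing that, WRCH (R = A/G,
    H = T/C/A). DGYW takes precedence when both match (the two motifs are
    reverse complements and can overlap on the same strand).
    """
    for motif in ("DGYW", "WRCH"):
        for start in range(pos - 3, pos + 1):
            if start < 0 or start + 4 > len(seq):
                continue
            if matches_iupac(seq[start : start + 4], motif):
                return motif
    return "none"


def longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """Return (length, start_a, start_b) of the longest common substring.

    Deterministic: on ties the leftmost occurrence in ``a``, then in ``b``,
    wins. Plain DP — callers only use it on short junction-sized strings.
    """
    best = (0, 0, 0)
    if not a or not b:
        return best
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best[0]:
                    best = (cur[j], i - cur[j], j - cur[j])
        prev = cur
    return best
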