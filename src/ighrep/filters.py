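"""Artifact removal: related-read collapse, singleton removal and the
Poisson cross-contamination filter.

Three error processes motivate the three rules. PCR/sequencing error on a
dominant clone produces low-frequency satellites with the same (or a
related) V gene and a near-identical CDR3 — satellites below 5% of their
dominant partner are removed. Sequences observed once cannot be
distinguished from error at all — singleton CDR3s are dropped. Barcode
synthesis errors convert one sample's barcode into another's at a rate of
about mu = 1/8000 (0.05 per position, three positions at Hamming distance
3); a CDR3 shared across samples is kept only when its count is too high
to be explained by such conversion, i.e. when the Poisson tail
probability P(X >= n) with lambda = N*mu falls below alpha = 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .align import Scoring, smith_waterman
from .clonotype import ClonotypeTable
from .reference import GermlineReference

DEFAULT_MU = 1.0 / 8000.0
DEFAULT_ALPHA = 1e-3


@dataclass
class RelatednessGraph:
    """Unordered V-pair relatedness under the >200 bp / <6 mismatch rule."""

    nodes: list[str]
    edges: dict[frozenset, tuple[int, int]]  # pair -> (aligned_match_len, n_mismatch)

    def related(self, a: str, b: str) -> bool:
        return a == b or frozenset((a, b)) in self.edges


def build_vh_relatedness(
    ref: GermlineReference, scoring: Scoring = Scoring()
) -> RelatednessGraph:
    """Pairwise-align all V segments; edge iff >200 matched and <6 mismatches.

    Both thresholds are strict, matching the stated rule: 200 matched
    bases or 6 mismatches do NOT qualify.
    """
    vs = ref.v_segments
    if len(vs) < 2:
        raise ValueError("relatedness needs at least two V segments")
    edges: dict[frozenset, tuple[int, int]] = {}
    for i, a in enumerate(vs):
        for b in vs[i + 1 :]:
            hit = smith_waterman(a.sequence, b.sequence, scoring)
            if hit.n_match > 200 and hit.n_mismatch < 6:
                edges[frozenset((a.id, b.id))] = (hit.n_match, hit.n_mismatch)
    return RelatednessGraph([v.id for v in vs], edges)


def _hamming_le(a: str, b: str, k: int) -> bool:
    if len(a) != len(b):
        return False
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > k:
                return False
    return True


def collapse_related_reads(
    table: ClonotypeTable,
    graph: RelatednessGraph,
    cdr3_max_mismatch: int = 1,
    minor_fraction: float = 0.05,
) -> tuple[ClonotypeTable, int]:
    """Remove low-frequency satellites of related dominant sequences.

    Two records are related when their V calls are related (or equal) and
    their equal-length CDR3s differ by at most ``cdr3_max_mismatch``. A
    minor record is removed when its count is strictly below
    ``minor_fraction`` of a related major's count (a minor at exactly 5%
    survives). Records are processed in descending count order; removed
    records cannot themselves remove others, and removed counts are not
    merged into the major. Returns (filtered table, n_removed).
    """
    records = table.records  # already sorted desc by copies, ties by cdr3
    # Hamming<=1 neighborhood via wildcard patterns, bucketed by length
    patterns: dict[str, list[int]] = {}
    for idx, r in enumerate(records):
        keys = {r.cdr3_nt}
        if cdr3_max_mismatch >= 1:
            for i in range(len(r.cdr3_nt)):
                keys.add(r.cdr3_nt[:i] + "*" + r.cdr3_nt[i + 1 :])
        for k in keys:
            patterns.setdefault(k, []).append(idx)

    removed: set[int] = set()
    for i, major in enumerate(records):
        if i in removed:
            continue
        cutoff = minor_fraction * major.copies
        keys = {major.cdr3_nt}
        if cdr3_max_mismatch >= 1:
            for p in range(len(major.cdr3_nt)):
                keys.add(major.cdr3_nt[:p] + "*" + major.cdr3_nt[p + 1 :])
        seen: set[int] = set()
        for k in keys:
            for jdx in patterns.get(k, ()):
                if jdx <= i or jdx in removed or jdx in seen:
                    continue
                seen.add(jdx)
                minor = records[jdx]
                if minor.copies >= cutoff:
                    continue
                if not graph.related(major.v_call, minor.v_call):
                    continue
                if _hamming_le(major.cdr3_nt, minor.cdr3_nt, cdr3_max_mismatch):
                    removed.add(jdx)
    kept = [r for idx, r in enumerate(records) if idx not in removed]
    return ClonotypeTable(table.sample_id, kept), len(removed)


def remove_singletons(table: ClonotypeTable) -> tuple[ClonotypeTable, int]:
    """Drop every CDR3 nucleotide sequence with a total count of one."""
    totals = table.cdr3_nt_counts()
    kept = [r for r in table.records if totals[r.cdr3_nt] > 1]
    return ClonotypeTable(table.sample_id, kept), len(table.records) - len(kept)


def contamination_p(
    n: int, N: int, mu: float = DEFAULT_MU, printed_formula: bool = False
) -> float:
    """Poisson upper-tail probability that cross-contamination explains n reads.

    With lambda = N*mu, returns P(X >= n) = 1 - sum_{k=0}^{n-1}
    e^{-lambda} lambda^k / k!. ``printed_formula=True`` starts the sum at
    k=1 instead (which makes P(X>=1) identically 1); the k=0 form is the
    standard survival function and the default. The result is clamped to
    [0, 1] against floating-point drift.
    """
    if n < 1 or N < 0 or not 0 < mu < 1:
        raise ValueError("require n >= 1, N >= 0, 0 < mu < 1")
    lam = N * mu
    p = float(stats.poisson.sf(n - 1, lam))
    if printed_formula:
        p += math.exp(-lam)
    return min(1.0, max(0.0, p))


@dataclass
class ContaminationTest:
    """One cross-sample CDR3 test: n recipient vs N source occurrences."""

    cdr3_nt: str
    sample_a: str  # recipient
    sample_b: str  # candidate source (largest co-occurring count)
    n: int
    N: int
    mu: float
    lam: float
    P: float
    verdict: str  # RETAIN | REMOVE


def filter_cross_contamination(
    samples: dict[str, ClonotypeTable],
    mu: float = DEFAULT_MU,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[dict[str, ClonotypeTable], list[ContaminationTest]]:
    """Test every CDR3 shared between samples of one run; keep if P < alpha.

    For each recipient sample the candidate source is the sample with the
    largest co-occurring count of the same CDR3 nucleotide sequence (the
    most conservative single-source model). CDR3s unique to one sample
    are never tested.
    """
    counts = {s: t.cdr3_nt_counts() for s, t in samples.items()}
    tests: list[ContaminationTest] = []
    removed_cdr3: dict[str, set[str]] = {s: set() for s in samples}
    all_cdr3: dict[str, list[str]] = {}
    for s, c in counts.items():
        for cdr3 in c:
            all_cdr3.setdefault(cdr3, []).append(s)
    for cdr3, present_in in sorted(all_cdr3.items()):
        if len(present_in) < 2:
            continue
        for recipient in present_in:
            n = counts[recipient][cdr3]
            source, N = max(
                ((s, counts[s][cdr3]) for s in present_in if s != recipient),
                key=lambda kv: (kv[1], kv[0]),
            )
            P = contamination_p(n, N, mu)
            verdict = "RETAIN" if P < alpha else "REMOVE"
            tests.append(
                ContaminationTest(cdr3, recipient, source, n, N, mu, N * mu, P, verdict)
            )
            if verdict == "REMOVE":
                removed_cdr3[recipient].add(cdr3)
    filtered = {
        s: ClonotypeTable(
            t.sample_id, [r for r in t.records if r.cdr3_nt not in removed_cdr3[s]]
        )
        for s, t in samples.items()
    }
    return filtered, tests


def contamination_report(tests: list[ContaminationTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cdr3": t.cdr3_nt,
                "recipient": t.sample_a,
                "source": t.sample_b,
                "n": t.n,
                "N": t.N,
                "lambda": t.lam,
                "P": t.P,
                "verdict": t.verdict,
            }
            for t in tests
        ]
    )


def apply_artifact_filters(
    samples: dict[str, ClonotypeTable],
    ref: GermlineReference,
    cdr3_max_mismatch: int = 1,
    minor_fraction: float = 0.05,
    mu: float = DEFAULT_MU,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[dict[str, ClonotypeTable], pd.DataFrame, pd.DataFrame]:
    """Run the full filter chain in its fixed order.

    collapse_related_reads -> remove_singletons -> filter_cross_contamination;
    total counts are non-increasing at every stage. Returns the filtered
    tables, a per-stage ledger and the contamination report.
    """
    graph = build_vh_relatedness(ref)
    ledger_rows = []
    stage1: dict[str, ClonotypeTable] = {}
    for s, t in samples.items():
        collapsed, n_rel = collapse_related_reads(
            t, graph, cdr3_max_mismatch, minor_fraction
        )
        desingled, n_single = remove_singletons(collapsed)
        stage1[s] = desingled
        ledger_rows.append(
            {
                "sample_id": s,
                "input_records": len(t),
                "removed_related": n_rel,
                "removed_singleton": n_single,
            }
        )
    filtered, tests = filter_cross_contamination(stage1, mu, alpha)
    for row in ledger_rows:
        s = row["sample_id"]
        row["removed_contamination"] = len(stage1[s]) - len(filtered[s])
        row["output_records"] = len(filtered[s])
    return filtered, pd.DataFrame(ledger_rows), contamination_report(tests)
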