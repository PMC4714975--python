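"""Repertoire statistics.

All the summary quantities the analysis reports on a clonotype table:

* D50 — the percentage of distinct CDR3s needed to cover half of all
  reads; 50 for a perfectly even repertoire, small for a clonal one.
* Pairwise CDR3-peptide sharing between two samples (unweighted, on
  distinct peptides).
* Normalized V_H usage — each distinct CDR3 nucleotide sequence counts
  once regardless of copy number, so clonal expansion does not distort
  gene usage; output ordered 5'->3' by chromosomal position.
* N-insertion profiles per distinct sequence, binned.
* Convergent-recombination entropy: for each CDR3 peptide encoded by n
  distinct V(D)J nucleotide recombinations with frequencies P_i,
  E = -sum P_i log2 P_i, binned into [0,0.5), [0.5,1.5), [1.5,2.5),
  [2.5,inf).
* Somatic-mutation summaries (percent of sequences with >=t changes and
  mutations per 10^4 bp over the CDR2->CDR3 window) on sequences with
  more than four copies.
* Isotype composition within mutation-count strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clonotype import ClonotypeTable
from .reference import GermlineReference

ENTROPY_BIN_EDGES = (0.0, 0.5, 1.5, 2.5, math.inf)
ENTROPY_BIN_LABELS = ("[0,0.5)", "[0.5,1.5)", "[1.5,2.5)", "[2.5,inf)")

N_INSERTION_BINS = ((0, 0), (1, 2), (3, 4), (5, 7), (8, None))

MUTATION_STRATA = ("0", "1", "2", "3", "4", ">=5")

UNSWITCHED = {"IgM", "IgD"}


def d50(table: ClonotypeTable) -> float:
    """Diversity index: (C / S) * 100.

    C is the smallest number of distinct CDR3 nucleotide sequences, taken
    in decreasing abundance order, whose cumulative reads reach at least
    half of all reads; S the number of distinct CDR3s. Rank ties are
    broken lexicographically for determinism.
    """
    counts = table.cdr3_nt_counts()
    if not counts:
        raise ValueError("d50 of an empty table is undefined")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(counts.values())
    acc = 0
    for c, (_, n) in enumerate(ranked, start=1):
        acc += n
        if 2 * acc >= total:
            return 100.0 * c / len(ranked)
    return 100.0  # unreachable


def pairwise_sharing(a: ClonotypeTable, b: ClonotypeTable) -> tuple[float, float]:
    """(pA->B, pB->A): percent of one sample's distinct CDR3 peptides found
    in the other. Computed on distinct peptides, unweighted by copies."""
    pa = {r.cdr3_aa for r in a.records if r.cdr3_aa}
    pb = {r.cdr3_aa for r in b.records if r.cdr3_aa}
    if not pa or not pb:
        raise ValueError("pairwise sharing needs non-empty peptide sets")
    inter = len(pa & pb)
    return 100.0 * inter / len(pa), 100.0 * inter / len(pb)


def pairwise_sharing_nt(a: ClonotypeTable, b: ClonotypeTable) -> tuple[float, float]:
    """Nucleotide-level sharing variant (non-default)."""
    pa = {r.cdr3_nt for r in a.records}
    pb = {r.cdr3_nt for r in b.records}
    if not pa or not pb:
        raise ValueError("pairwise sharing needs non-empty tables")
    inter = len(pa & pb)
    return 100.0 * inter / len(pa), 100.0 * inter / len(pb)


def vh_usage(
    table: ClonotypeTable,
    ref: GermlineReference | None = None,
    normalized: bool = True,
) -> pd.Series:
    """Per-V_H percentages, ordered 5'->3' along the chromosome when a
    reference is given.

    Normalized mode counts each distinct CDR3 nucleotide sequence once
    under its V call; raw mode weights by copies.
    """
    if not table.records:
        raise ValueError("vh_usage of an empty table is undefined")
    if normalized:
        seen: dict[str, str] = {}
        for r in table.records:  # descending copies: dominant record wins
            seen.setdefault(r.cdr3_nt, r.v_call)
        counts = pd.Series(list(seen.values())).value_counts()
    else:
        counts = (
            pd.Series({id(r): r.v_call for r in table.records})
            .to_frame("v")
            .assign(w=[r.copies for r in table.records])
            .groupby("v")["w"]
            .sum()
        )
    pct = 100.0 * counts / counts.sum()
    if ref is not None:
        order = [v.id for v in sorted(ref.v_segments, key=lambda s: s.chromosomal_order)]
        pct = pct.reindex(order, fill_value=0.0)
    else:
        pct = pct.sort_index()
    pct.name = "percent"
    return pct


def n_insertion_profile(
    table: ClonotypeTable,
    bins: tuple[tuple[int, int | None], ...] = N_INSERTION_BINS,
) -> pd.Series:
    """Percent of distinct sequences per total-N bin (n1 + n2).

    Each distinct CDR3 nucleotide sequence counts once regardless of copy
    number, using its dominant record's junction.
    """
    if not table.records:
        raise ValueError("n_insertion_profile of an empty table is undefined")
    n_by_cdr3: dict[str, int] = {}
    for r in table.records:
        n_by_cdr3.setdefault(r.cdr3_nt, r.n_total)
    values = np.array(list(n_by_cdr3.values()))
    out = {}
    for lo, hi in bins:
        label = (
            f"{lo}" if hi == lo else (f">={lo}" if hi is None else f"{lo}-{hi}")
        )
        mask = values >= lo if hi is None else (values >= lo) & (values <= hi)
        out[label] = 100.0 * mask.sum() / values.size
    return pd.Series(out, name="percent")


@dataclass
class ConvergenceResult:
    per_peptide: pd.DataFrame  # cdr3_aa, n_recombinations, entropy, bin
    bin_fractions: pd.Series  # % of distinct peptides per entropy range
    bin_fractions_weighted: pd.Series  # read-weighted variant


def convergence_entropy(
    table: ClonotypeTable, weight: str = "copies"
) -> ConvergenceResult:
    """Entropy of V(D)J recombination usage per CDR3 peptide.

    A recombination is a distinct (v_call, d_call, j_call, cdr3_nt)
    tuple. ``weight="copies"`` (default) takes P_i as read-frequency
    within the peptide; ``weight="unique"`` weights each recombination
    equally.
    """
    if weight not in ("copies", "unique"):
        raise ValueError("weight must be 'copies' or 'unique'")
    groups: dict[str, dict[tuple, int]] = {}
    reads: dict[str, int] = {}
    for r in table.records:
        if not r.cdr3_aa:
            continue
        key = (r.v_call, r.d_call, r.j_call, r.cdr3_nt)
        g = groups.setdefault(r.cdr3_aa, {})
        g[key] = g.get(key, 0) + (r.copies if weight == "copies" else 1)
        reads[r.cdr3_aa] = reads.get(r.cdr3_aa, 0) + r.copies
    if not groups:
        raise ValueError("no productive CDR3 peptides in table")
    rows = []
    for aa in sorted(groups):
        w = np.array(list(groups[aa].values()), dtype=float)
        p = w / w.sum()
        ent = float(-(p * np.log2(p)).sum())
        ent = max(ent, 0.0)
        idx = np.searchsorted(ENTROPY_BIN_EDGES[1:], ent, side="right")
        rows.append(
            {
                "cdr3_aa": aa,
                "n_recombinations": len(w),
                "entropy": ent,
                "bin": ENTROPY_BIN_LABELS[idx],
                "reads": reads[aa],
            }
        )
    df = pd.DataFrame(rows)
    frac = (
        df["bin"].value_counts().reindex(ENTROPY_BIN_LABELS, fill_value=0)
        / len(df)
        * 100.0
    )
    wfrac = (
        df.groupby("bin")["reads"].sum().reindex(ENTROPY_BIN_LABELS, fill_value=0)
        / df["reads"].sum()
        * 100.0
    )
    frac.name = wfrac.name = "percent"
    return ConvergenceResult(df, frac, wfrac)


@dataclass
class MutationSummary:
    percent_by_threshold: dict[int, float]
    rate_per_10kb: float
    n_eligible: int


def mutation_summary(
    table: ClonotypeTable,
    thresholds: tuple[int, ...] = (1, 2, 4),
    min_copies: int = 5,
) -> MutationSummary | None:
    """Mutation load over eligible records (copies >= min_copies).

    Percentages are fractions of eligible unique sequences with at least
    t mutations; the rate is 10^4 * (total mutations) / (total window
    length). Returns ``None`` when no record is eligible (reported as
    absent, not zero).
    """
    elig = [
        r
        for r in table.records
        if r.mutation_count is not None and r.copies >= min_copies
    ]
    if not elig:
        return None
    pct = {
        t: 100.0 * sum(r.mutation_count >= t for r in elig) / len(elig)
        for t in thresholds
    }
    total_window = sum(r.window_len for r in elig)
    rate = 1e4 * sum(r.mutation_count for r in elig) / total_window
    return MutationSummary(pct, rate, len(elig))


def isotype_by_mutation(
    table: ClonotypeTable, min_copies: int = 5
) -> dict[str, pd.DataFrame]:
    """Isotype composition within mutation strata.

    Returns ``by_stratum`` (% of each isotype within mutation-count
    strata 0,1,2,3,4,>=5 — each row sums to 100), ``by_status`` (the same
    split into non-mutated vs mutated), and ``switched`` (% of
    class-switched sequences, isotype not IgM/IgD, per stratum).
    """
    elig = [
        r
        for r in table.records
        if r.mutation_count is not None and r.copies >= min_copies and r.isotype
    ]
    if not elig:
        raise ValueError("no eligible records for isotype cross-tabulation")

    def stratum(mc: int) -> str:
        return str(mc) if mc < 5 else ">=5"

    df = pd.DataFrame(
        {
            "isotype": [r.isotype for r in elig],
            "stratum": [stratum(r.mutation_count) for r in elig],
            "status": [
                "mutated" if r.mutation_count >= 1 else "non-mutated" for r in elig
            ],
        }
    )
    by_stratum = (
        pd.crosstab(df["stratum"], df["isotype"], normalize="index") * 100.0
    ).reindex([s for s in MUTATION_STRATA if s in set(df["stratum"])])
    by_status = pd.crosstab(df["status"], df["isotype"], normalize="index") * 100.0
    switched = (
        df.assign(sw=~df["isotype"].isin(UNSWITCHED))
        .groupby("stratum")["sw"]
        .mean()
        .mul(100.0)
        .reindex([s for s in MUTATION_STRATA if s in set(df["stratum"])])
    )
    switched.name = "percent_switched"
    return {"by_stratum": by_stratum, "by_status": by_status, "switched": switched}


def metrics_tidy(
    table: ClonotypeTable, ref: GermlineReference | None = None
) -> pd.DataFrame:
    """All metrics for one sample as a tidy (metric, stratum, value) frame."""
    rows = [
        {"metric": "d50", "stratum": "", "value": d50(table)},
        {"metric": "total_copies", "stratum": "", "value": table.total_copies},
        {"metric": "distinct_cdr3_nt", "stratum": "", "value": table.distinct_cdr3_nt},
        {"metric": "distinct_cdr3_aa", "stratum": "", "value": table.distinct_cdr3_aa},
    ]
    for v, pct in vh_usage(table, ref).items():
        rows.append({"metric": "vh_usage", "stratum": v, "value": pct})
    for b, pct in n_insertion_profile(table).items():
        rows.append({"metric": "n_insertion", "stratum": b, "value": pct})
    try:
        conv = convergence_entropy(table)
        for b, pct in conv.bin_fractions.items():
            rows.append({"metric": "entropy_bin", "stratum": b, "value": pct})
    except ValueError:
        pass
    ms = mutation_summary(table)
    if ms is not None:
        for t, pct in ms.percent_by_threshold.items():
            rows.append({"metric": "pct_mutated", "stratum": f">={t}", "value": pct})
        rows.append({"metric": "mutations_per_10kb", "stratum": "", "value": ms.rate_per_10kb})
    out = pd.DataFrame(rows)
    out.insert(0, "sample_id", table.sample_id)
    return out
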