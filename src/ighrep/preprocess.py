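"""Demultiplexing, quality trimming and read-pair merging.

The three steps mirror the assay's primary analysis exactly:

* demultiplex by *exact* 6-nt barcode match at the 5' end of the
  constant-region (reverse) read — no 1-mismatch rescue, because the
  downstream contamination model treats misassignment as full barcode
  conversion at rate mu = 1/8000;
* trim each mate with a 2-base sliding quality window: at the first
  window holding any quality below 20, the read is truncated from the
  window start to the 3' end;
* merge mates by their maximal end overlap and keep the pair only if the
  overlap is perfect — a single mismatch discards both mates rather than
  consensus-calling them.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .barcodes import BarcodeSet
from .dna import revcomp


@dataclass
class ReadPair:
    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: list[int]
    rev_qual: list[int]

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(
            self.rev_qual
        ):
            raise ValueError("sequence/quality length mismatch")


@dataclass
class MergedRead:
    id: str
    sample_id: str
    seq: str
    overlap_len: int


class MergeFailure(Enum):
    NO_OVERLAP = "NO_OVERLAP"
    MISMATCH = "MISMATCH"
    TOO_SHORT = "TOO_SHORT"


@dataclass
class Rejected:
    id: str
    reason: MergeFailure


def demultiplex(
    pairs: Iterable[ReadPair],
    barcodes: BarcodeSet,
    sample_ids: Sequence[str] | None = None,
) -> tuple[dict[str, list[ReadPair]], list[ReadPair]]:
    """Assign pairs to samples by exact barcode prefix on the reverse read.

    Returns (assigned, unassigned); assigned pairs have the barcode bases
    stripped from sequence and qualities. ``sample_ids`` defaults to
    "S1", "S2", ... in barcode order.
    """
    if len(barcodes) == 0:
        raise ValueError("empty barcode set")
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(len(barcodes))]
    if len(sample_ids) != len(barcodes):
        raise ValueError("one sample id per barcode required")
    lookup = dict(zip(barcodes, sample_ids))
    n = barcodes.length
    assigned: dict[str, list[ReadPair]] = {s: [] for s in sample_ids}
    unassigned: list[ReadPair] = []
    for pair in pairs:
        sample = lookup.get(pair.rev_seq[:n])
        if sample is None:
            unassigned.append(pair)
            continue
        assigned[sample].append(
            ReadPair(
                pair.id,
                pair.fwd_seq,
                pair.rev_seq[n:],
                pair.fwd_qual,
                pair.rev_qual[n:],
            )
        )
    return assigned, unassigned


def quality_trim(
    seq: str, qual: Sequence[int], window: int = 2, threshold: int = 20
) -> tuple[str, list[int]]:
    """Truncate at the first sliding window containing a sub-threshold base.

    Windows (i, ..., i+window-1) are scanned left to right; at the first
    window with any quality < threshold the read is cut to [0, i). Reads
    shorter than the window are returned unchanged.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(seq) < window:
        return seq, list(qual)
    for i in range(len(seq) - window + 1):
        if any(q < threshold for q in qual[i : i + window]):
            return seq[:i], list(qual[:i])
    return seq, list(qual)


def merge_pair(
    fwd: str,
    rev: str,
    min_overlap: int = 15,
    read_id: str = "",
    sample_id: str = "",
) -> MergedRead | Rejected:
    """Merge a mate pair over its maximal perfect end overlap.

    ``rev`` is supplied in sequencing orientation and reverse-complemented
    here. The merged sequence is returned only if the largest suffix of
    the forward read equal to a prefix of the reverse-complemented mate is
    at least ``min_overlap`` long and mismatch/gap free; otherwise the
    pair is rejected with a reason (TOO_SHORT when no overlap of the
    required length is even geometrically possible, MISMATCH when the
    best-scoring overlap of sufficient length contains mismatches,
    NO_OVERLAP otherwise).
    """
    rc = revcomp(rev)
    max_k = min(len(fwd), len(rc))
    if max_k < min_overlap:
        return Rejected(read_id, MergeFailure.TOO_SHORT)
    for k in range(max_k, min_overlap - 1, -1):
        if fwd[len(fwd) - k :] == rc[:k]:
            return MergedRead(read_id, sample_id, fwd + rc[k:], k)
    # diagnose: exhaustive shift scoring (matches - mismatches)
    best_score, best_k = None, 0
    for k in range(1, max_k + 1):
        a, b = fwd[len(fwd) - k :], rc[:k]
        matches = sum(x == y for x, y in zip(a, b))
        score = 2 * matches - k
        if best_score is None or score > best_score:
            best_score, best_k = score, k
    if best_k >= min_overlap:
        return Rejected(read_id, MergeFailure.MISMATCH)
    return Rejected(read_id, MergeFailure.NO_OVERLAP)


def _open_maybe_gz(path: str | Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(
    fwd_path: str | Path, rev_path: str | Path
) -> Iterator[ReadPair]:
    """Stream mate pairs from two FASTQ files (optionally gzipped)."""
    with _open_maybe_gz(fwd_path) as f1, _open_maybe_gz(rev_path) as f2:
        for r1, r2 in zip(
            SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq"), strict=True
        ):
            if r1.id != r2.id:
                raise ValueError(f"mate id mismatch: {r1.id} vs {r2.id}")
            yield ReadPair(
                r1.id,
                str(r1.seq),
                str(r2.seq),
                r1.letter_annotations["phred_quality"],
                r2.letter_annotations["phred_quality"],
            )


def preprocess_run(
    fwd_path: str | Path,
    rev_path: str | Path,
    barcodes: BarcodeSet,
    sample_ids: Sequence[str] | None = None,
    window: int = 2,
    threshold: int = 20,
    min_overlap: int = 15,
    min_length: int = 100,
) -> tuple[dict[str, list[MergedRead]], dict[str, dict[str, int]]]:
    """Demultiplex, trim and merge one paired-end run.

    Returns per-sample merged reads plus a per-sample ledger of counts:
    assigned, dropped_short (post-trim length below ``min_length``),
    merged, and one counter per merge-failure reason. Unassigned pairs are
    tallied under the pseudo-sample ``"unassigned"``.
    """
    assigned, unassigned = demultiplex(
        read_fastq_pairs(fwd_path, rev_path), barcodes, sample_ids
    )
    merged: dict[str, list[MergedRead]] = {}
    stats: dict[str, dict[str, int]] = {
        "unassigned": {"assigned": len(unassigned)}
    }
    for sample, pairs in assigned.items():
        out: list[MergedRead] = []
        tally = {
            "assigned": len(pairs),
            "dropped_short": 0,
            "merged": 0,
            **{f.value: 0 for f in MergeFailure},
        }
        for pair in pairs:
            fseq, _ = quality_trim(pair.fwd_seq, pair.fwd_qual, window, threshold)
            rseq, _ = quality_trim(pair.rev_seq, pair.rev_qual, window, threshold)
            if len(fseq) < min_length or len(rseq) < min_length:
                tally["dropped_short"] += 1
                continue
            result = merge_pair(fseq, rseq, min_overlap, pair.id, sample)
            if isinstance(result, MergedRead):
                out.append(result)
                tally["merged"] += 1
            else:
                tally[result.reason.value] += 1
        merged[sample] = out
        stats[sample] = tally
    return merged, stats
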