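"""V(D)J segment assignment, CDR3 boundary migration and mutation calling.

Each merged read is mapped locally against every germline V; the J is the
best hit downstream of the V alignment, the constant segment (isotype
call) the best hit downstream of the J. CDR boundary positions stored on
the reference segments are then migrated onto the read through the
alignment edit strings, the junction is decomposed under the canonical
template-first convention of :mod:`ighrep.junction`, and somatic
mutations are called as aligned mismatches within the window from the
CDR2 start to the CDR3 start — the stretch the assay's primers leave
untouched. Mutation statistics only ever use sequences seen in more than
four copies, which suppresses residual sequencing-error artifacts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import AlignmentHit, Scoring, smith_waterman, sw_score
from .dna import hotspot_class, translate
from .junction import decompose_gap
from .preprocess import MergedRead
from .reference import GermlineReference, GermlineSegment


class UnmappedRead(Exception):
    """V or J could not be called above the score floor."""


class FailedMigration(Exception):
    """A CDR boundary projected outside the read."""


@dataclass(frozen=True)
class AnnotateConfig:
    scoring: Scoring = Scoring()
    v_min_score: int = 60
    j_min_score: int = 20
    c_min_score: int = 20
    d_min_match: int = 5
    p_max: int = 2
    min_copies: int = 5  # sequences with copies < this are excluded from SHM stats


@dataclass
class AnnotatedSequence:
    """One unique merged sequence with calls, junction and mutations."""

    seq: str
    sample_id: str
    copies: int
    v_call: str
    d_call: str | None
    j_call: str
    isotype: str
    cdr2_start: int
    cdr3_start: int
    cdr3_end: int
    cdr3_nt: str
    cdr3_aa: str
    productive: bool
    v_del: int = 0
    d5_del: int = 0
    d3_del: int = 0
    j_del: int = 0
    n1_len: int = 0
    n2_len: int = 0
    p1: str = ""
    p2: str = ""
    mutations: list[tuple[int, str, str, str]] = field(default_factory=list)
    mutation_count: int | None = None  # None = not evaluated (copies too low)
    window_len: int = 0
    v_hit: AlignmentHit | None = field(default=None, repr=False)
    j_hit: AlignmentHit | None = field(default=None, repr=False)

    @property
    def n_total(self) -> int:
        return self.n1_len + self.n2_len


def _best_hit(
    seq: str,
    segments: Sequence[GermlineSegment],
    scoring: Scoring,
    offset: int = 0,
) -> AlignmentHit | None:
    """Highest-scoring segment over a (sub)window; catalog order breaks ties."""
    window = seq[offset:]
    if not window:
        return None
    # rank candidates with the fast scores-only kernel; the full alignment
    # (boundaries + edit string) is computed for the winner only
    best_seg, best_score = None, 0
    for seg in segments:
        score = sw_score(window, seg.sequence, scoring)
        if score > best_score:
            best_seg, best_score = seg, score
    if best_seg is None:
        return None
    hit = smith_waterman(window, best_seg.sequence, scoring, best_seg.id)
    return hit.shifted(offset) if offset else hit


def project(hit: AlignmentHit, ref_pos: int) -> int:
    """Map a reference position onto the query through the edit string.

    Positions outside the aligned reference interval are extrapolated
    diagonally; positions falling in a deletion map to the next query base.
    """
    if ref_pos < hit.ref_start:
        return hit.query_start - (hit.ref_start - ref_pos)
    if ref_pos >= hit.ref_end:
        return hit.query_end + (ref_pos - hit.ref_end)
    for op, q, r in hit.columns():
        if op in "=XD" and r == ref_pos:
            return q
    return hit.query_end  # unreachable for well-formed cigars


def assign_segments(
    read: MergedRead | str,
    ref: GermlineReference,
    config: AnnotateConfig = AnnotateConfig(),
    sample_id: str = "",
    copies: int = 1,
) -> AnnotatedSequence:
    """Call V, J, C (and boundaries); raises :class:`UnmappedRead` on failure.

    The D call is made later, during junction reconstruction, where the
    inter-template gap is known.
    """
    if isinstance(read, MergedRead):
        seq, sample_id = read.seq, read.sample_id or sample_id
    else:
        seq = read
    if not seq:
        raise UnmappedRead("empty sequence")
    sc = config.scoring

    v_hit = _best_hit(seq, ref.v_segments, sc)
    if v_hit is None or v_hit.score < config.v_min_score:
        raise UnmappedRead("no V hit above score floor")
    j_hit = _best_hit(seq, ref.j_segments, sc, offset=v_hit.query_end)
    if j_hit is None or j_hit.score < config.j_min_score:
        raise UnmappedRead("no J hit downstream of V")
    c_hit = _best_hit(seq, ref.c_segments, sc, offset=j_hit.query_end)
    isotype = ""
    if c_hit is not None and c_hit.score >= config.c_min_score:
        isotype = c_hit.segment_id

    return AnnotatedSequence(
        seq=seq,
        sample_id=sample_id,
        copies=copies,
        v_call=v_hit.segment_id,
        d_call=None,
        j_call=j_hit.segment_id,
        isotype=isotype,
        cdr2_start=0,
        cdr3_start=0,
        cdr3_end=0,
        cdr3_nt="",
        cdr3_aa="",
        productive=False,
        v_hit=v_hit,
        j_hit=j_hit,
    )


def migrate_cdr3(
    annot: AnnotatedSequence, ref: GermlineReference
) -> AnnotatedSequence:
    """Project CDR2/CDR3 boundaries from the reference onto the read.

    The CDR3 runs from the V segment's mark (just after the conserved Cys
    codon, as stored in the sidecar) to the J segment's mark. Out-of-frame
    or stop-containing CDR3s are kept but flagged unproductive with an
    empty peptide.
    """
    v = ref[annot.v_call]
    j = ref[annot.j_call]
    cdr2 = project(annot.v_hit, v.cdr_marks[1])
    cdr3s = project(annot.v_hit, v.cdr_marks[2])
    cdr3e = project(annot.j_hit, j.cdr3_mark)
    if not (0 <= cdr2 < cdr3s < cdr3e <= len(annot.seq)):
        raise FailedMigration(
            f"boundaries ({cdr2}, {cdr3s}, {cdr3e}) outside read of length {len(annot.seq)}"
        )
    annot.cdr2_start, annot.cdr3_start, annot.cdr3_end = cdr2, cdr3s, cdr3e
    annot.cdr3_nt = annot.seq[cdr3s:cdr3e]
    if len(annot.cdr3_nt) % 3 == 0:
        aa = translate(annot.cdr3_nt)
        if "*" not in aa:
            annot.cdr3_aa, annot.productive = aa, True
        else:
            annot.cdr3_aa, annot.productive = "", False
    else:
        annot.cdr3_aa, annot.productive = "", False
    return annot


def reconstruct_junction(
    annot: AnnotatedSequence,
    ref: GermlineReference,
    config: AnnotateConfig = AnnotateConfig(),
) -> AnnotatedSequence:
    """Fill deletions, P and N fields (and the D call) for one read.

    Template matches are extended maximally beyond the alignment ends
    before the remaining gap is decomposed; when V and J template claims
    overlap, the V wins and the J's deletion count absorbs the difference.
    """
    v = ref[annot.v_call]
    j = ref[annot.j_call]
    seq = annot.seq

    # V template: within the V's CDR3 portion the template must match the
    # germline exactly and contiguously — a local alignment may bridge a
    # mismatch to grab chance matches inside the junction, which would
    # violate the canonical exact-extension convention
    qe, re_ = annot.v_hit.query_end, annot.v_hit.ref_end
    for op, qq, rr in annot.v_hit.columns():
        if op != "=" and rr >= v.cdr3_mark:
            qe, re_ = qq, rr
            break
    else:
        while qe < len(seq) and re_ < len(v.sequence) and seq[qe] == v.sequence[re_]:
            qe += 1
            re_ += 1
    v_del = len(v.sequence) - re_

    # J template: symmetric rule on the J's CDR3 portion
    qs, rs = annot.j_hit.query_start, annot.j_hit.ref_start
    cut = None
    for op, qq, rr in annot.j_hit.columns():
        if op != "=" and rr < j.cdr3_mark:
            cut = (qq + (op in "=XI"), rr + (op in "=XD"))
    if cut is not None:
        qs, rs = cut
    else:
        while qs > qe and rs > 0 and seq[qs - 1] == j.sequence[rs - 1]:
            qs -= 1
            rs -= 1
    if qs < qe:  # overlapping template claims: V takes precedence
        rs += qe - qs
        qs = qe
    j_del = rs

    gap = seq[qe:qs]
    decomp = decompose_gap(
        gap, v.sequence, v_del, j.sequence, j_del,
        ref.d_segments, config.d_min_match, config.p_max,
    )
    annot.v_del, annot.j_del = v_del, j_del
    annot.d_call = decomp.d_id
    annot.d5_del, annot.d3_del = decomp.d5_del, decomp.d3_del
    annot.n1_len, annot.n2_len = decomp.n1_len, decomp.n2_len
    annot.p1, annot.p2 = decomp.p1, decomp.p2
    return annot


def call_mutations(
    annot: AnnotatedSequence,
    ref: GermlineReference,
    min_copies: int = 5,
) -> AnnotatedSequence:
    """Call substitutions vs the best germline V within [CDR2, CDR3).

    Sequences with fewer than ``min_copies`` copies are flagged
    not-evaluated (``mutation_count=None``) and never enter mutation
    statistics. Each mutation carries the AID hotspot class of its
    germline 4-mer context (DGYW / WRCH / none).
    """
    v = ref[annot.v_call]
    window = range(annot.cdr2_start, annot.cdr3_start)
    annot.window_len = len(window)
    if annot.copies < min_copies or not window:
        annot.mutation_count = None
        annot.mutations = []
        return annot
    muts: list[tuple[int, str, str, str]] = []
    for op, q, r in annot.v_hit.columns():
        if op == "X" and q in window:
            muts.append(
                (q, v.sequence[r], annot.seq[q], hotspot_class(v.sequence, r))
            )
    annot.mutations = muts
    annot.mutation_count = len(muts)
    return annot


def annotate_unique_sequences(
    counts: dict[str, int],
    ref: GermlineReference,
    sample_id: str,
    config: AnnotateConfig = AnnotateConfig(),
) -> tuple[list[AnnotatedSequence], dict[str, int]]:
    """Annotate unique sequences (with copy counts) for one sample.

    Returns the annotated records (descending copy count, ties by
    sequence) and a ledger of exclusions.
    """
    log = {"input": len(counts), "annotated": 0, "unmapped": 0, "failed_migration": 0}
    records: list[AnnotatedSequence] = []
    for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        try:
            annot = assign_segments(seq, ref, config, sample_id, copies=n)
            migrate_cdr3(annot, ref)
            reconstruct_junction(annot, ref, config)
            call_mutations(annot, ref, config.min_copies)
        except UnmappedRead:
            log["unmapped"] += 1
            continue
        except FailedMigration:
            log["failed_migration"] += 1
            continue
        records.append(annot)
        log["annotated"] += 1
    return records, log


def annotate_sample(
    reads: Iterable[MergedRead | str],
    ref: GermlineReference,
    sample_id: str,
    config: AnnotateConfig = AnnotateConfig(),
) -> tuple[list[AnnotatedSequence], dict[str, int]]:
    """Deduplicate merged reads, then annotate each unique sequence once."""
    counts: Counter[str] = Counter(
        r.seq if isinstance(r, MergedRead) else r for r in reads
    )
    return annotate_unique_sequences(dict(counts), ref, sample_id, config)
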