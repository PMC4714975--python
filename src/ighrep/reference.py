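"""Germline V/D/J/C segment catalogs.

A :class:`GermlineReference` plays the role the IMGT download plays for
real data: it carries the segment sequences together with the CDR
boundary marks that the annotator migrates onto reads. The synthetic
generator (:func:`generate_reference`) builds catalogs with the size
constraints a mouse IgH locus imposes on the analysis — V segments long
enough for the relatedness rule to be meaningful, D segments short enough
to be partially unidentifiable after trimming — and always contains at
least one pair of near-identical V genes so the related-read collapse is
exercised.

Coordinate conventions (0-based): for V segments ``cdr_marks`` are the
start positions of CDR1, CDR2 and CDR3, where the CDR3 start points just
*after* the conserved Cys codon; for J segments the single mark is the
half-open end of the CDR3 portion, just *before* the conserved Trp codon.
CDR3 peptides therefore read like the field prints them ("ARGAY",
"MRYSNYWYFDV") without the flanking C and W.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import BASES

KINDS = ("V", "D", "J", "C")

DEFAULT_ISOTYPES = ("IgM", "IgD", "IgG1", "IgG3", "IgG2b", "IgG2c", "IgE", "IgA")

#: V length and fixed architecture used by the synthetic catalog.
V_LEN = 294
V_CDR_MARKS = (78, 150, 285)  # CDR1 start, CDR2 start, CDR3 start (after Cys)
J_CDR3_PART = 15  # J bases belonging to CDR3, followed by the Trp codon + FR4
J_FR4_LEN = 30
C_LEN = 90

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class GermlineSegment:
    id: str
    kind: str
    family: str
    sequence: str
    cdr_marks: tuple[int, ...] | None
    chromosomal_order: int

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.sequence:
            raise ValueError("segment sequence must be non-empty")
        if self.cdr_marks is not None:
            marks = tuple(self.cdr_marks)
            if any(m2 <= m1 for m1, m2 in zip(marks, marks[1:])):
                raise ValueError("cdr_marks must be strictly increasing")
            if marks[0] < 0 or marks[-1] > len(self.sequence):
                raise ValueError("cdr_marks out of sequence bounds")
            self.cdr_marks = marks

    @property
    def cdr3_mark(self) -> int:
        """CDR3 start (V) or CDR3 end (J) position on the segment."""
        if self.kind == "V":
            return self.cdr_marks[2]
        if self.kind == "J":
            return self.cdr_marks[0]
        raise ValueError(f"{self.kind} segments carry no CDR3 mark")


class GermlineReference:
    """Indexed catalog of germline segments."""

    def __init__(self, segments: list[GermlineSegment]):
        self.segments = list(segments)
        self._by_id = {s.id: s for s in self.segments}
        if len(self._by_id) != len(self.segments):
            raise ValueError("duplicate segment ids in reference")

    def __getitem__(self, seg_id: str) -> GermlineSegment:
        return self._by_id[seg_id]

    def __contains__(self, seg_id: str) -> bool:
        return seg_id in self._by_id

    def of_kind(self, kind: str) -> list[GermlineSegment]:
        return [s for s in self.segments if s.kind == kind]

    @property
    def v_segments(self) -> list[GermlineSegment]:
        return self.of_kind("V")

    @property
    def d_segments(self) -> list[GermlineSegment]:
        return self.of_kind("D")

    @property
    def j_segments(self) -> list[GermlineSegment]:
        return self.of_kind("J")

    @property
    def c_segments(self) -> list[GermlineSegment]:
        return self.of_kind("C")

    # ---- serialization: FASTA + sidecar TSV of marks/metadata ----

    def write(self, fasta_path: str | Path, sidecar_path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s.sequence), id=s.id, description=s.kind)
            for s in self.segments
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        with open(sidecar_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id", "kind", "family", "chromosomal_order", "cdr_marks"])
            for s in self.segments:
                marks = ",".join(map(str, s.cdr_marks)) if s.cdr_marks else ""
                w.writerow([s.id, s.kind, s.family, s.chromosomal_order, marks])

    @classmethod
    def read(cls, fasta_path: str | Path, sidecar_path: str | Path) -> "GermlineReference":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        segments = []
        with open(sidecar_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                marks = (
                    tuple(int(x) for x in row["cdr_marks"].split(","))
                    if row["cdr_marks"]
                    else None
                )
                segments.append(
                    GermlineSegment(
                        id=row["id"],
                        kind=row["kind"],
                        family=row["family"],
                        sequence=seqs[row["id"]],
                        cdr_marks=marks,
                        chromosomal_order=int(row["chromosomal_order"]),
                    )
                )
        return cls(segments)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random codons avoiding stop codons (keeps reading frames clean)."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list(BASES), 3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _mutate_positions(rng: np.random.Generator, seq: str, positions) -> str:
    s = list(seq)
    for p in positions:
        s[p] = rng.choice([b for b in BASES if b != s[p]])
    return "".join(s)


DEFAULT_V_FAMILIES = ("V1", "V2", "V3", "V5", "V6", "V11", "V12", "V14")


def generate_reference(
    n_v: int | dict[str, int] = 10,
    n_d: int = 4,
    n_j: int = 4,
    isotypes: tuple[str, ...] = DEFAULT_ISOTYPES,
    seed: int = 0,
) -> GermlineReference:
    """Generate a deterministic synthetic germline segment catalog.

    ``n_v`` may be a total count (spread over the default families) or a
    family -> count mapping. The first family always receives at least two
    members: the second is a copy of the first with exactly three point
    differences, so the pair is "related" under the artifact filter's
    >200 bp / <6 mismatch rule, while independently drawn V segments are
    not (random 294-mers share ~25% identity).
    """
    if isinstance(n_v, int):
        counts: dict[str, int] = {}
        fams = list(DEFAULT_V_FAMILIES)
        for i in range(n_v):
            fam = fams[i % len(fams)]
            counts[fam] = counts.get(fam, 0) + 1
    else:
        counts = dict(n_v)
    if sum(counts.values()) < 2:
        raise ValueError("need at least two V segments (relatedness untestable)")
    if min(n_d, n_j) < 1 or len(isotypes) < 1:
        raise ValueError("segment counts must be >= 1")

    rng = np.random.default_rng(seed)
    segments: list[GermlineSegment] = []
    order = 0

    first_fam = next(iter(counts))
    related_template: str | None = None
    for fam, k in counts.items():
        for i in range(k):
            name = f"{fam}-{2 + 3 * order}"
            if fam == first_fam and i == 1 and related_template is not None:
                # near-identical paralog: 3 substitutions outside the
                # conserved architecture positions
                pos = rng.choice(np.arange(10, V_CDR_MARKS[2] - 10), 3, replace=False)
                seq = _mutate_positions(rng, related_template, sorted(pos))
            else:
                # codon-aligned body, conserved Cys codon before the CDR3 mark
                body = _random_codons(rng, V_CDR_MARKS[2] // 3 - 1)
                tail = _random_codons(rng, (V_LEN - V_CDR_MARKS[2]) // 3)
                seq = body + "TGT" + tail
                if fam == first_fam and i == 0:
                    related_template = seq
            segments.append(
                GermlineSegment(name, "V", fam, seq, V_CDR_MARKS, order)
            )
            order += 1

    for i in range(n_d):
        length = int(rng.integers(10, 26))
        seq = "".join(rng.choice(list(BASES), length))
        segments.append(
            GermlineSegment(f"D{1 + i % 4}-{1 + i}", "D", f"D{1 + i % 4}", seq, None, order)
        )
        order += 1

    for i in range(n_j):
        cdr3_part = _random_codons(rng, J_CDR3_PART // 3)
        fr4 = _random_codons(rng, J_FR4_LEN // 3)
        seq = cdr3_part + "TGG" + fr4
        segments.append(
            GermlineSegment(f"J{i + 1}", "J", "J", seq, (J_CDR3_PART,), order)
        )
        order += 1

    for iso in isotypes:
        seq = "".join(rng.choice(list(BASES), C_LEN))
        segments.append(GermlineSegment(iso, "C", iso, seq, None, order))
        order += 1

    return GermlineReference(segments)
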