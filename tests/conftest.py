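"""Shared fixtures: synthetic references and record factories."""

from __future__ import annotations

import numpy as np
import pytest

from ighrep.annotate import AnnotatedSequence
from ighrep.clonotype import ClonotypeTable
from ighrep.reference import (
    GermlineReference,
    GermlineSegment,
    V_CDR_MARKS,
    generate_reference,
)

BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def random_codons(rng: np.random.Generator, n: int) -> str:
    out = []
    while len(out) < n:
        c = "".join(rng.choice(list(BASES), 3))
        if c not in _STOPS:
            out.append(c)
    return "".join(out)


@pytest.fixture(scope="session")
def ref10() -> GermlineReference:
    """Standard 10V/4D/4J/8C synthetic catalog (includes a related V pair)."""
    return generate_reference(10, 4, 4, seed=1)


def build_v(name: str, family: str, tail9: str, rng, order: int = 0) -> GermlineSegment:
    """A 294-nt V with standard marks whose CDR3 contribution is ``tail9``."""
    assert len(tail9) == 9
    body = random_codons(rng, V_CDR_MARKS[2] // 3 - 1)
    return GermlineSegment(name, "V", family, body + "TGT" + tail9, V_CDR_MARKS, order)


def build_j(name: str, cdr3_part: str, rng, order: int = 0) -> GermlineSegment:
    assert len(cdr3_part) % 3 == 0
    fr4 = random_codons(rng, 10)
    return GermlineSegment(
        name, "J", "J", cdr3_part + "TGG" + fr4, (len(cdr3_part),), order
    )


@pytest.fixture(scope="session")
def figure_ref() -> GermlineReference:
    """Handcrafted catalog whose V11-2 + D2-6 + J1 rearrangement encodes the
    CDR3 peptide MRYSNYWYFDV with no trimming and no N additions."""
    rng = np.random.default_rng(42)
    v11 = build_v("V11-2", "V11", "ATGCGTTAT", rng, order=0)  # ...C | M R Y
    v_other = build_v("V1-2", "V1", random_codons(rng, 3), rng, order=1)
    d26 = GermlineSegment("D2-6", "D", "D2", "TCCAACTACTGG", None, 2)  # S N Y W
    d_other = GermlineSegment("D1-1", "D", "D1", "GGGACTAGCATCA", None, 3)
    j1 = build_j("J1", "TATTTTGATGTC", rng, order=4)  # Y F D V
    j2 = build_j("J2", random_codons(rng, 4), rng, order=5)
    igm = GermlineSegment(
        "IgM", "C", "IgM", "".join(rng.choice(list(BASES), 90)), None, 6
    )
    igg = GermlineSegment(
        "IgG1", "C", "IgG1", "".join(rng.choice(list(BASES), 90)), None, 7
    )
    return GermlineReference([v11, v_other, d26, d_other, j1, j2, igm, igg])


def make_record(
    cdr3_nt: str = "GCTCGTGGTGCTTAT",
    cdr3_aa: str = "ARGAY",
    v_call: str = "V1-2",
    d_call: str | None = "D1-1",
    j_call: str = "J1",
    isotype: str = "IgM",
    copies: int = 10,
    n1_len: int = 0,
    n2_len: int = 0,
    mutation_count: int | None = 0,
    window_len: int = 135,
    seq: str | None = None,
    sample_id: str = "S1",
) -> AnnotatedSequence:
    """Minimal annotated record for metrics/filter tests."""
    return AnnotatedSequence(
        seq=seq if seq is not None else f"{v_call}|{cdr3_nt}|{j_call}|{isotype}",
        sample_id=sample_id,
        copies=copies,
        v_call=v_call,
        d_call=d_call,
        j_call=j_call,
        isotype=isotype,
        cdr2_start=150,
        cdr3_start=285,
        cdr3_end=285 + len(cdr3_nt),
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        productive=bool(cdr3_aa),
        n1_len=n1_len,
        n2_len=n2_len,
        mutation_count=mutation_count,
        window_len=window_len,
    )


def make_table(records, sample_id: str = "S1") -> ClonotypeTable:
    return ClonotypeTable(sample_id, records)
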