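"""Per-sample clonotype tables.

A :class:`ClonotypeTable` aggregates the unique annotated sequences of
one sample with their copy counts. Three totals recur throughout the
analysis and figure legends:

* ``total_copies`` — total clean reads (the CNT role),
* ``distinct_cdr3_nt`` — unique CDR3 nucleotide sequences (CNU),
* ``distinct_cdr3_aa`` — unique CDR3 peptides (CPU).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .annotate import AnnotatedSequence

_COLUMNS = [
    "sequence_id",
    "sequence",
    "duplicate_count",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "productive",
    "cdr3",
    "cdr3_aa",
    "cdr2_start",
    "cdr3_start",
    "cdr3_end",
    "v_del",
    "d5_del",
    "d3_del",
    "j_del",
    "n1_length",
    "n2_length",
    "np_total",
    "mutation_count",
    "window_length",
    "mutations",
]


class ClonotypeTable:
    def __init__(self, sample_id: str, records: Iterable[AnnotatedSequence]):
        self.sample_id = sample_id
        self.records: list[AnnotatedSequence] = sorted(
            records, key=lambda r: (-r.copies, r.cdr3_nt, r.seq)
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def total_copies(self) -> int:
        return sum(r.copies for r in self.records)

    @property
    def distinct_cdr3_nt(self) -> int:
        return len({r.cdr3_nt for r in self.records})

    @property
    def distinct_cdr3_aa(self) -> int:
        return len({r.cdr3_aa for r in self.records if r.cdr3_aa})

    def cdr3_nt_counts(self) -> dict[str, int]:
        """Total copies per distinct CDR3 nucleotide sequence."""
        out: dict[str, int] = {}
        for r in self.records:
            out[r.cdr3_nt] = out.get(r.cdr3_nt, 0) + r.copies
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.records):
            rows.append(
                {
                    "sequence_id": f"{self.sample_id}-{i:06d}",
                    "sequence": r.seq,
                    "duplicate_count": r.copies,
                    "v_call": r.v_call,
                    "d_call": r.d_call or "",
                    "j_call": r.j_call,
                    "c_call": r.isotype,
                    "productive": r.productive,
                    "cdr3": r.cdr3_nt,
                    "cdr3_aa": r.cdr3_aa,
                    "cdr2_start": r.cdr2_start,
                    "cdr3_start": r.cdr3_start,
                    "cdr3_end": r.cdr3_end,
                    "v_del": r.v_del,
                    "d5_del": r.d5_del,
                    "d3_del": r.d3_del,
                    "j_del": r.j_del,
                    "n1_length": r.n1_len,
                    "n2_length": r.n2_len,
                    "np_total": r.n_total,
                    "mutation_count": (
                        "" if r.mutation_count is None else r.mutation_count
                    ),
                    "window_length": r.window_len,
                    "mutations": ";".join(
                        f"{p}:{a}>{b}:{h}" for p, a, b, h in r.mutations
                    ),
                }
            )
        return pd.DataFrame(rows, columns=_COLUMNS)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, sample_id: str, df: pd.DataFrame) -> "ClonotypeTable":
        records = []
        for row in df.itertuples(index=False):
            muts = []
            if isinstance(row.mutations, str) and row.mutations:
                for tok in row.mutations.split(";"):
                    pos, change, cls_ = tok.split(":")
                    records_from, records_to = change.split(">")
                    muts.append((int(pos), records_from, records_to, cls_))
            mc = row.mutation_count
            mc = None if (mc == "" or pd.isna(mc)) else int(mc)
            records.append(
                AnnotatedSequence(
                    seq=row.sequence,
                    sample_id=sample_id,
                    copies=int(row.duplicate_count),
                    v_call=row.v_call,
                    d_call=row.d_call or None,
                    j_call=row.j_call,
                    isotype=row.c_call if isinstance(row.c_call, str) else "",
                    cdr2_start=int(row.cdr2_start),
                    cdr3_start=int(row.cdr3_start),
                    cdr3_end=int(row.cdr3_end),
                    cdr3_nt=row.cdr3,
                    cdr3_aa=row.cdr3_aa if isinstance(row.cdr3_aa, str) else "",
                    productive=bool(row.productive),
                    v_del=int(row.v_del),
                    d5_del=int(row.d5_del),
                    d3_del=int(row.d3_del),
                    j_del=int(row.j_del),
                    n1_len=int(row.n1_length),
                    n2_len=int(row.n2_length),
                    mutations=muts,
                    mutation_count=mc,
                    window_len=int(row.window_length),
                )
            )
        return cls(sample_id, records)

    @classmethod
    def read_tsv(cls, sample_id: str, path: str | Path) -> "ClonotypeTable":
        df = pd.read_csv(
            path, sep="\t", keep_default_na=False,
            dtype={"cdr3": str, "cdr3_aa": str, "mutations": str, "d_call": str,
                   "c_call": str, "mutation_count": str},
        )
        return cls.from_dataframe(sample_id, df)
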