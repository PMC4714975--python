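"""Artifact filters: relatedness thresholds, collapse, singletons, Poisson."""

import math
import random

import numpy as np
import pytest

from ighrep.clonotype import ClonotypeTable
from ighrep.filters import (
    RelatednessGraph,
    build_vh_relatedness,
    collapse_related_reads,
    contamination_p,
    filter_cross_contamination,
    remove_singletons,
)
from ighrep.reference import GermlineReference, GermlineSegment

from conftest import make_record, make_table
from oracles import poisson_upper_tail


def v_pair_reference(seq_a, seq_b):
    return GermlineReference(
        [
            GermlineSegment("Va", "V", "V1", seq_a, None, 0),
            GermlineSegment("Vb", "V", "V2", seq_b, None, 1),
        ]
    )


def mutate_at(seq, positions):
    flip = {"A": "G", "G": "A", "C": "T", "T": "C"}
    s = list(seq)
    for p in positions:
        s[p] = flip[s[p]]
    return "".join(s)


class TestRelatedness:
    SEQ = "".join(random.Random(0).choice("ACGT") for _ in range(250))

    def test_identical_pair_related(self):
        g = build_vh_relatedness(v_pair_reference(self.SEQ, self.SEQ))
        assert g.related("Va", "Vb")
        assert g.edges[frozenset(("Va", "Vb"))] == (250, 0)

    def test_three_mismatches_related(self):
        g = build_vh_relatedness(
            v_pair_reference(self.SEQ, mutate_at(self.SEQ, [50, 120, 200]))
        )
        assert g.related("Va", "Vb")

    def test_exactly_six_mismatches_not_related(self):
        b = mutate_at(self.SEQ, [40, 80, 120, 160, 200, 240])
        g = build_vh_relatedness(v_pair_reference(self.SEQ, b))
        assert not g.related("Va", "Vb")

    def test_exactly_200_matched_not_related(self):
        # identical 200-mers share exactly 200 matched bases: not > 200
        s200 = self.SEQ[:200]
        g = build_vh_relatedness(v_pair_reference(s200, s200))
        assert not g.related("Va", "Vb")

    def test_short_alignment_not_related(self):
        rng = random.Random(3)
        other = self.SEQ[:150] + "".join(rng.choice("ACGT") for _ in range(100))
        g = build_vh_relatedness(v_pair_reference(self.SEQ, other))
        assert not g.related("Va", "Vb")

    def test_v_related_to_itself(self):
        g = RelatednessGraph(["Va"], {})
        assert g.related("Va", "Va")


GRAPH = RelatednessGraph(["Va", "Vb", "Vc"], {frozenset(("Va", "Vb")): (250, 2)})


def related_cdr3(base="GCTCGTGGTGCTTAT", pos=0):
    flip = {"A": "G", "G": "A", "C": "T", "T": "C"}
    return base[:pos] + flip[base[pos]] + base[pos + 1 :]


class TestCollapse:
    def test_minor_below_five_percent_removed(self):
        t = make_table(
            [
                make_record(copies=1000, v_call="Va"),
                make_record(cdr3_nt=related_cdr3(), copies=40, v_call="Vb"),
            ]
        )
        out, n = collapse_related_reads(t, GRAPH)
        assert n == 1
        assert [r.copies for r in out.records] == [1000]

    def test_minor_at_or_above_five_percent_retained(self):
        for minor in (50, 60):  # exactly 5% and 6%
            t = make_table(
                [
                    make_record(copies=1000, v_call="Va"),
                    make_record(cdr3_nt=related_cdr3(), copies=minor, v_call="Vb"),
                ]
            )
            out, n = collapse_related_reads(t, GRAPH)
            assert n == 0, minor
            assert len(out.records) == 2

    def test_unrelated_v_not_collapsed(self):
        t = make_table(
            [
                make_record(copies=1000, v_call="Va"),
                make_record(copies=10, v_call="Vc"),  # same CDR3, unrelated V
            ]
        )
        out, n = collapse_related_reads(t, GRAPH)
        assert n == 0

    def test_same_v_counts_as_related(self):
        t = make_table(
            [
                make_record(copies=1000, v_call="Vc"),
                make_record(cdr3_nt=related_cdr3(), copies=10, v_call="Vc"),
            ]
        )
        out, n = collapse_related_reads(t, GRAPH)
        assert n == 1

    def test_cdr3_distance_two_not_collapsed(self):
        far = related_cdr3(related_cdr3(), pos=5)
        t = make_table(
            [
                make_record(copies=1000, v_call="Va"),
                make_record(cdr3_nt=far, copies=10, v_call="Va"),
            ]
        )
        out, n = collapse_related_reads(t, GRAPH)
        assert n == 0

    def test_removed_minor_cannot_remove_others(self):
        # descending processing: the 1000-copy major removes the 30-copy
        # minor; the removed minor must not then remove the 2-copy record
        # that only it could have removed... the major still can, so use
        # distance-2 from major, distance-1 from minor.
        base = "GCTCGTGGTGCTTAT"
        minor = related_cdr3(base, 0)
        tiny = related_cdr3(minor, 5)  # d(base, tiny) = 2
        t = make_table(
            [
                make_record(cdr3_nt=base, copies=1000, v_call="Va"),
                make_record(cdr3_nt=minor, copies=30, v_call="Va"),
                make_record(cdr3_nt=tiny, copies=2, v_call="Va"),
            ]
        )
        out, n = collapse_related_reads(t, GRAPH)
        assert n == 1
        assert {r.cdr3_nt for r in out.records} == {base, tiny}


class TestSingletons:
    def test_single_copy_cdr3_removed_two_retained(self):
        t = make_table(
            [
                make_record(copies=1),
                make_record(cdr3_nt="TTTCGTGGTGCTTAT", copies=2),
            ]
        )
        out, n = remove_singletons(t)
        assert n == 1
        assert [r.copies for r in out.records] == [2]

    def test_split_records_summing_above_one_retained(self):
        # same CDR3 seen in two distinct sequences of one copy each: total 2
        t = make_table(
            [
                make_record(copies=1, seq="seqA"),
                make_record(copies=1, seq="seqB"),
            ]
        )
        out, n = remove_singletons(t)
        assert n == 0

    def test_empty_table(self):
        out, n = remove_singletons(make_table([]))
        assert len(out.records) == 0 and n == 0


class TestContaminationP:
    def test_closed_form_lambda_one(self):
        p = contamination_p(1, 8000, 1 / 8000)
        assert math.isclose(p, 1 - math.exp(-1), rel_tol=1e-12)

    def test_zero_source_reads(self):
        assert contamination_p(1, 0, 1 / 8000) == 0.0

    def test_printed_variant_saturates_at_one(self):
        # summing from k=1 leaves out the k=0 term: P(X>=1) becomes 1
        assert contamination_p(1, 8000, 1 / 8000, printed_formula=True) == 1.0

    def test_matches_partial_sum_oracle(self):
        rng = random.Random(17)
        for _ in range(200):
            n = rng.randint(1, 20)
            N = rng.randint(0, 100_000)
            p = contamination_p(n, N, 1 / 8000)
            assert abs(p - poisson_upper_tail(n, N / 8000)) < 1e-12

    def test_monotone_in_n_and_N(self):
        ps = [contamination_p(n, 8000, 1 / 8000) for n in range(1, 10)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        qs = [contamination_p(3, N, 1 / 8000) for N in (0, 100, 1000, 10000)]
        assert all(a <= b for a, b in zip(qs, qs[1:]))

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            contamination_p(0, 10, 1 / 8000)
        with pytest.raises(ValueError):
            contamination_p(1, 10, 0.0)


class TestCrossSampleFilter:
    def _tables(self, counts_a, counts_b):
        recs_a = [
            make_record(cdr3_nt=c, copies=n, seq=f"A{c}") for c, n in counts_a.items()
        ]
        recs_b = [
            make_record(cdr3_nt=c, copies=n, seq=f"B{c}", sample_id="S2")
            for c, n in counts_b.items()
        ]
        return {"S1": ClonotypeTable("S1", recs_a), "S2": ClonotypeTable("S2", recs_b)}

    def test_private_cdr3_never_tested(self):
        samples = self._tables({"AAACCC": 1}, {"GGGTTT": 9000})
        filtered, tests = filter_cross_contamination(samples)
        assert tests == []
        assert len(filtered["S1"].records) == 1

    def test_high_count_shared_cdr3_retained(self):
        samples = self._tables({"AAACCC": 50}, {"AAACCC": 8000})
        filtered, tests = filter_cross_contamination(samples)
        by = {(t.sample_a, t.cdr3_nt): t for t in tests}
        t = by[("S1", "AAACCC")]
        assert t.lam == 1.0 and t.verdict == "RETAIN"
        assert any(r.cdr3_nt == "AAACCC" for r in filtered["S1"].records)

    def test_low_count_shared_cdr3_removed(self):
        samples = self._tables({"AAACCC": 1, "CCCGGG": 40}, {"AAACCC": 8000})
        filtered, tests = filter_cross_contamination(samples)
        t = next(x for x in tests if x.sample_a == "S1" and x.cdr3_nt == "AAACCC")
        assert t.P == pytest.approx(1 - math.exp(-1), rel=1e-9)
        assert t.verdict == "REMOVE"
        assert {r.cdr3_nt for r in filtered["S1"].records} == {"CCCGGG"}

    def test_counts_non_increasing(self):
        samples = self._tables(
            {"AAACCC": 3, "CCCGGG": 500}, {"AAACCC": 5000, "CCCGGG": 2}
        )
        filtered, _ = filter_cross_contamination(samples)
        for s in samples:
            assert filtered[s].total_copies <= samples[s].total_copies


def test_type_one_error_rate_alpha_consistent():
    """Counts drawn from the contamination null Poisson(N*mu) survive the
    filter at a rate consistent with alpha (99% binomial CI at 1e4 trials)."""
    rng = np.random.default_rng(99)
    N, mu, alpha = 8000, 1 / 8000, 1e-3
    draws = rng.poisson(N * mu, size=10_000)
    retained = sum(
        contamination_p(int(n), N, mu) < alpha for n in draws if n >= 1
    )
    frac = retained / draws.size
    half = 2.576 * math.sqrt(alpha * (1 - alpha) / draws.size)
    assert frac <= alpha + half
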