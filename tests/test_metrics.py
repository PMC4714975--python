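"""Repertoire statistics: closed forms, normalization and invariants."""

import math

import numpy as np
import pytest

from ighrep.clonotype import ClonotypeTable
from ighrep.metrics import (
    convergence_entropy,
    d50,
    isotype_by_mutation,
    mutation_summary,
    n_insertion_profile,
    pairwise_sharing,
    vh_usage,
)
from ighrep.reference import generate_reference

from conftest import make_record, make_table


def cdr3(i):
    # distinct in-frame 15-mers
    alphabet = "ACGT"
    tag = "".join(alphabet[(i // 4**k) % 4] for k in range(6))
    return "GCTCGTGGT" + tag + "TAT"


def aa(i):
    return f"AR{i}"


class TestD50:
    def test_uniform_even_table_gives_fifty(self):
        t = make_table([make_record(cdr3_nt=cdr3(i), copies=10) for i in range(10)])
        assert d50(t) == 50.0

    def test_dominant_clone(self):
        recs = [make_record(cdr3_nt=cdr3(0), copies=60)]
        recs += [make_record(cdr3_nt=cdr3(i + 1), copies=1) for i in range(40)]
        assert d50(make_table(recs)) == pytest.approx(100.0 / 41.0)

    def test_single_clonotype_is_hundred(self):
        assert d50(make_table([make_record(copies=7)])) == 100.0

    @pytest.mark.parametrize("scale", [2, 5, 100])
    def test_invariant_under_copy_rescaling(self, scale):
        counts = [17, 9, 9, 3, 1, 1]
        a = make_table(
            [make_record(cdr3_nt=cdr3(i), copies=c) for i, c in enumerate(counts)]
        )
        b = make_table(
            [
                make_record(cdr3_nt=cdr3(i), copies=c * scale)
                for i, c in enumerate(counts)
            ]
        )
        assert d50(a) == d50(b)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            d50(make_table([]))


class TestSharing:
    def test_identical_tables_share_fully(self):
        t = make_table(
            [make_record(cdr3_nt=cdr3(i), cdr3_aa=aa(i)) for i in range(5)]
        )
        assert pairwise_sharing(t, t) == (100.0, 100.0)

    def test_disjoint_tables_share_nothing(self):
        a = make_table([make_record(cdr3_aa=aa(1))])
        b = make_table([make_record(cdr3_aa=aa(2))])
        assert pairwise_sharing(a, b) == (0.0, 0.0)

    def test_asymmetric_percentages(self):
        a = make_table(
            [make_record(cdr3_nt=cdr3(i), cdr3_aa=p) for i, p in
             enumerate(["X", "Y", "Z", "W"])]
        )
        b = make_table(
            [make_record(cdr3_nt=cdr3(i + 10), cdr3_aa=p) for i, p in
             enumerate(["X", "Q"])]
        )
        assert pairwise_sharing(a, b) == (25.0, 50.0)

    def test_swap_symmetry(self):
        a = make_table(
            [make_record(cdr3_nt=cdr3(i), cdr3_aa=aa(i)) for i in range(6)]
        )
        b = make_table(
            [make_record(cdr3_nt=cdr3(i), cdr3_aa=aa(i)) for i in range(3, 9)]
        )
        pab, pba = pairwise_sharing(a, b)
        qba, qab = pairwise_sharing(b, a)
        assert (pab, pba) == (qab, qba)


class TestVhUsage:
    def test_all_one_v(self):
        t = make_table([make_record(v_call="V11-2") for _ in range(3)])
        usage = vh_usage(t)
        assert usage["V11-2"] == 100.0

    def test_normalized_ignores_copies(self):
        recs = [
            make_record(cdr3_nt=cdr3(0), v_call="V1-55", copies=100),
            make_record(cdr3_nt=cdr3(1), v_call="V1-55", copies=1),
            make_record(cdr3_nt=cdr3(2), v_call="V1-55", copies=1),
            make_record(cdr3_nt=cdr3(3), v_call="V6-6", copies=2),
        ]
        usage = vh_usage(make_table(recs))
        assert usage["V1-55"] == 75.0 and usage["V6-6"] == 25.0

    def test_raw_mode_weights_by_copies(self):
        recs = [
            make_record(cdr3_nt=cdr3(0), v_call="V1-55", copies=300),
            make_record(cdr3_nt=cdr3(1), v_call="V6-6", copies=100),
        ]
        usage = vh_usage(make_table(recs), normalized=False)
        assert usage["V1-55"] == 75.0

    def test_sums_to_hundred_and_chromosomal_order(self, ref10):
        v_ids = [v.id for v in ref10.v_segments]
        recs = [
            make_record(cdr3_nt=cdr3(i), v_call=v_ids[i % len(v_ids)])
            for i in range(17)
        ]
        usage = vh_usage(make_table(recs), ref10)
        assert usage.sum() == pytest.approx(100.0, abs=1e-9)
        order = [
            v.id for v in sorted(ref10.v_segments, key=lambda s: s.chromosomal_order)
        ]
        assert list(usage.index) == order


class TestNInsertionProfile:
    def test_zero_insertions_all_in_first_bin(self):
        t = make_table(
            [make_record(cdr3_nt=cdr3(i), n1_len=0, n2_len=0) for i in range(5)]
        )
        profile = n_insertion_profile(t)
        assert profile["0"] == 100.0

    def test_binning_and_sum(self):
        totals = [0, 1, 2, 3, 4, 5, 7, 8, 12]
        t = make_table(
            [
                make_record(cdr3_nt=cdr3(i), n1_len=n, n2_len=0)
                for i, n in enumerate(totals)
            ]
        )
        profile = n_insertion_profile(t)
        assert profile.sum() == pytest.approx(100.0, abs=1e-9)
        assert profile["0"] == pytest.approx(100 / 9)
        assert profile["1-2"] == pytest.approx(200 / 9)
        assert profile[">=8"] == pytest.approx(200 / 9)


class TestConvergenceEntropy:
    def test_single_recombination_zero_entropy(self):
        t = make_table([make_record(cdr3_nt=cdr3(0), cdr3_aa="ARX")])
        res = convergence_entropy(t)
        row = res.per_peptide.iloc[0]
        assert row.entropy == 0.0 and row.bin == "[0,0.5)"

    @pytest.mark.parametrize("k,expected", [(2, 1.0), (4, 2.0), (8, 3.0)])
    def test_uniform_recombinations_give_log2_k(self, k, expected):
        t = make_table(
            [
                make_record(cdr3_nt=cdr3(i), cdr3_aa="ARX", copies=5)
                for i in range(k)
            ]
        )
        res = convergence_entropy(t)
        assert res.per_peptide.iloc[0].entropy == pytest.approx(expected)

    def test_bins_and_bounds(self):
        # 50/50 -> 1.0 in [0.5,1.5); 25x4 -> 2.0 in [1.5,2.5)
        t1 = make_table(
            [make_record(cdr3_nt=cdr3(i), cdr3_aa="ARX", copies=10) for i in range(2)]
        )
        assert convergence_entropy(t1).per_peptide.iloc[0].bin == "[0.5,1.5)"
        t2 = make_table(
            [make_record(cdr3_nt=cdr3(i), cdr3_aa="ARX", copies=10) for i in range(4)]
        )
        assert convergence_entropy(t2).per_peptide.iloc[0].bin == "[1.5,2.5)"

    def test_copy_weighted_vs_unique_weighted(self):
        t = make_table(
            [
                make_record(cdr3_nt=cdr3(0), cdr3_aa="ARX", copies=99),
                make_record(cdr3_nt=cdr3(1), cdr3_aa="ARX", copies=1),
            ]
        )
        skewed = convergence_entropy(t, weight="copies").per_peptide.iloc[0].entropy
        uniform = convergence_entropy(t, weight="unique").per_peptide.iloc[0].entropy
        assert skewed < uniform == 1.0

    def test_entropy_bounded_by_log2_n(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(30):
            recs.append(
                make_record(
                    cdr3_nt=cdr3(i), cdr3_aa=f"AR{i % 7}",
                    copies=int(rng.integers(1, 50)),
                )
            )
        res = convergence_entropy(make_table(recs))
        for row in res.per_peptide.itertuples():
            assert 0.0 <= row.entropy <= math.log2(row.n_recombinations) + 1e-12
        assert res.bin_fractions.sum() == pytest.approx(100.0, abs=1e-9)


class TestMutationSummary:
    def test_thresholds(self):
        counts = [0, 1, 2, 5]
        t = make_table(
            [
                make_record(cdr3_nt=cdr3(i), mutation_count=c, copies=10)
                for i, c in enumerate(counts)
            ]
        )
        ms = mutation_summary(t)
        assert ms.percent_by_threshold == {1: 75.0, 2: 50.0, 4: 25.0}

    def test_rate_per_10kb(self):
        t = make_table(
            [
                make_record(cdr3_nt=cdr3(0), mutation_count=2, copies=10,
                            window_len=100),
                make_record(cdr3_nt=cdr3(1), mutation_count=0, copies=10,
                            window_len=100),
            ]
        )
        assert mutation_summary(t).rate_per_10kb == pytest.approx(100.0)

    def test_unmutated_table_all_zero(self):
        t = make_table(
            [make_record(cdr3_nt=cdr3(i), mutation_count=0, copies=9)
             for i in range(4)]
        )
        ms = mutation_summary(t)
        assert set(ms.percent_by_threshold.values()) == {0.0}
        assert ms.rate_per_10kb == 0.0

    def test_low_copy_records_excluded(self):
        t = make_table(
            [
                make_record(cdr3_nt=cdr3(0), mutation_count=3, copies=4),
                make_record(cdr3_nt=cdr3(1), mutation_count=None, copies=2),
            ]
        )
        assert mutation_summary(t) is None


class TestIsotypeByMutation:
    def test_all_igm_never_switched(self):
        t = make_table(
            [
                make_record(cdr3_nt=cdr3(i), isotype="IgM", mutation_count=i % 3,
                            copies=8)
                for i in range(9)
            ]
        )
        out = isotype_by_mutation(t)
        assert (out["switched"] == 0.0).all()
        for _, row in out["by_stratum"].iterrows():
            assert row.sum() == pytest.approx(100.0, abs=1e-9)

    def test_switching_enriched_among_mutated(self):
        recs = []
        for i in range(20):
            mutated = i % 2 == 0
            recs.append(
                make_record(
                    cdr3_nt=cdr3(i),
                    isotype="IgG1" if (mutated and i % 4 == 0) else "IgM",
                    mutation_count=3 if mutated else 0,
                    copies=10,
                )
            )
        out = isotype_by_mutation(make_table(recs))
        by_status = out["by_status"]
        assert by_status.loc["mutated", "IgG1"] > 0.0
        assert "IgG1" not in by_status.columns or (
            by_status.loc["non-mutated"].get("IgG1", 0.0) == 0.0
        )
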