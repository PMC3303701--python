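import math

import numpy as np
import pytest
from scipy import stats

from oracles import brute_sp_tc, exact_signed_rank_p
from tmcoffee.errors import DataError
from tmcoffee.evaluate import (paired_test, score_suite, sp_score, tc_score)
from tmcoffee.formats import CoreAnnotation, MultipleAlignment


def _full_core(msa):
    return CoreAnnotation.whole_columns(msa.ids, [(0, msa.ncols)],
                                        columns=msa.ncols)


REF3 = MultipleAlignment(("a", "b", "c"), ("MKWV", "MKWV", "MKWV"))


class TestSP:
    def test_identity_gives_one(self):
        sp, pairs = sp_score(REF3, REF3, _full_core(REF3))
        assert sp == 1.0
        assert pairs == 12  # 4 columns x 3 pairs

    def test_hand_enumeration(self):
        # break c's first column in the test MSA: of the 3 pairs in ref
        # column 0, only (a0,b0) survives -> 1/3 in that column
        test = MultipleAlignment(("a", "b", "c"),
                                 ("MKWV-", "MKWV-", "-MKWV"))
        core = CoreAnnotation.whole_columns(REF3.ids, [(0, 1)], columns=4)
        sp, pairs = sp_score(test, REF3, core)
        assert pairs == 3
        assert sp == pytest.approx(1 / 3)

    def test_empty_core_flagged(self):
        core = CoreAnnotation({sid: () for sid in REF3.ids}, columns=4)
        sp, pairs = sp_score(REF3, REF3, core)
        assert pairs == 0
        assert math.isnan(sp)

    def test_id_mismatch_error(self):
        other = MultipleAlignment(("a", "b", "z"), ("MKWV", "MKWV", "MKWV"))
        with pytest.raises(DataError):
            sp_score(other, REF3, _full_core(REF3))

    def test_residue_mismatch_error(self):
        other = MultipleAlignment(("a", "b", "c"), ("MKWI", "MKWV", "MKWV"))
        with pytest.raises(DataError):
            sp_score(other, REF3, _full_core(REF3))


class TestTC:
    def test_identity_gives_one(self):
        tc, cols = tc_score(REF3, REF3, _full_core(REF3))
        assert tc == 1.0
        assert cols == 4

    def test_one_broken_column_of_four(self):
        test = MultipleAlignment(("a", "b", "c"),
                                 ("MKWV-", "MKWV-", "MKW-V"))
        tc, cols = tc_score(test, REF3, _full_core(REF3))
        assert cols == 4
        assert tc == pytest.approx(0.75)

    def test_gap_column_insertion_invariant(self):
        test = MultipleAlignment(("a", "b", "c"),
                                 ("MK--WV", "MK--WV", "MK--WV"))
        assert tc_score(test, REF3, _full_core(REF3))[0] == 1.0
        assert sp_score(test, REF3, _full_core(REF3))[0] == 1.0

    def test_row_shuffle_invariant(self):
        test = MultipleAlignment(("c", "a", "b"), ("MKWV", "MKWV", "MKWV"))
        assert tc_score(test, REF3, _full_core(REF3))[0] == 1.0


def _random_instance(rng):
    """Random reference + perturbed test alignment over the same sequences."""
    nrows = int(rng.integers(2, 5))
    ncols = int(rng.integers(3, 8))
    letters = "MKWVFA"
    ids = tuple(f"s{k}" for k in range(nrows))
    ref_rows = []
    for _ in range(nrows):
        row = "".join(rng.choice(list(letters), size=ncols))
        # punch random gaps, keep at least one residue
        row = list(row)
        for c in range(ncols):
            if rng.random() < 0.25 and sum(ch != "-" for ch in row) > 1:
                row[c] = "-"
        ref_rows.append("".join(row))
    ref = MultipleAlignment(ids, tuple(ref_rows))
    # test: realign each degapped row by inserting gaps at random positions
    width = ncols + 3
    test_rows = []
    for row in ref_rows:
        res = row.replace("-", "")
        slots = sorted(rng.choice(width, size=len(res), replace=False))
        out = ["-"] * width
        for ch, c in zip(res, slots):
            out[c] = ch
        test_rows.append("".join(out))
    test = MultipleAlignment(ids, tuple(test_rows))
    spans = []
    c = int(rng.integers(0, ncols))
    spans.append((0, c + 1))
    core = CoreAnnotation.whole_columns(ids, spans, columns=ncols)
    return test, ref, core


def _random_instance_full_columns(rng):
    """Random gap-free reference (every core column carries all rows) plus
    a perturbed test alignment.  TC <= SP is only a theorem when counted
    columns all have the same residue count, which this layout guarantees."""
    nrows = int(rng.integers(2, 5))
    ncols = int(rng.integers(3, 8))
    ids = tuple(f"s{k}" for k in range(nrows))
    ref_rows = tuple("".join(rng.choice(list("MKWVFA"), size=ncols))
                     for _ in range(nrows))
    ref = MultipleAlignment(ids, ref_rows)
    width = ncols + 3
    test_rows = []
    for row in ref_rows:
        slots = sorted(rng.choice(width, size=ncols, replace=False))
        out = ["-"] * width
        for ch, c in zip(row, slots):
            out[c] = ch
        test_rows.append("".join(out))
    test = MultipleAlignment(ids, tuple(test_rows))
    core = CoreAnnotation.whole_columns(
        ids, [(0, int(rng.integers(1, ncols + 1)))], columns=ncols)
    return test, ref, core


class TestAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_set_based_oracle(self, seed):
        rng = np.random.default_rng(seed)
        test, ref, core = _random_instance(rng)
        masks = {sid: core.mask(sid, ref.ncols) for sid in ref.ids}
        b_sp, b_pairs, b_tc, b_cols = brute_sp_tc(
            dict(zip(test.ids, test.rows)), dict(zip(ref.ids, ref.rows)),
            masks)
        sp, pairs = sp_score(test, ref, core)
        tc, cols = tc_score(test, ref, core)
        assert pairs == b_pairs and cols == b_cols
        if pairs:
            assert sp == pytest.approx(b_sp)
        if cols:
            assert tc == pytest.approx(b_tc)

    @pytest.mark.parametrize("seed", range(30))
    def test_tc_le_sp_on_full_columns(self, seed):
        rng = np.random.default_rng(1000 + seed)
        test, ref, core = _random_instance_full_columns(rng)
        sp, pairs = sp_score(test, ref, core)
        tc, cols = tc_score(test, ref, core)
        if pairs and cols:
            assert tc <= sp + 1e-12

    def test_tc_can_exceed_sp_with_uneven_columns(self):
        # with unequal core-column occupancy TC <= SP is NOT a theorem: a
        # recovered 2-residue column plus a broken many-pair column tips it
        ref = MultipleAlignment(("a", "b", "c", "d"),
                                ("MM", "MM", "-M", "-M"))
        test = MultipleAlignment(("a", "b", "c", "d"),
                                 ("MM--", "M--M", "-M--", "--M-"))
        core = CoreAnnotation.whole_columns(ref.ids, [(0, 2)], columns=2)
        sp, _ = sp_score(test, ref, core)
        tc, _ = tc_score(test, ref, core)
        assert tc > sp


class TestScoreSuite:
    def test_single_family_aggregate(self):
        rep = score_suite({"f1": (REF3, REF3, _full_core(REF3))})
        assert rep.avg_sp == 1.0 and rep.avg_tc == 1.0
        assert rep.total_pairs == 12 and rep.total_cols == 4

    def test_mean_of_two_families(self):
        t1 = MultipleAlignment(("a", "b", "c"), ("MKWV-", "MKWV-", "MKW-V"))
        rep = score_suite({
            "f1": (t1, REF3, _full_core(REF3)),      # TC 0.75
            "f2": (REF3, REF3, _full_core(REF3)),    # TC 1.0
        })
        assert rep.avg_tc == pytest.approx((0.75 + 1.0) / 2)
        assert rep.total_cols == 8

    def test_tsv_round_numbers(self):
        rep = score_suite({"f1": (REF3, REF3, _full_core(REF3))})
        text = rep.to_tsv()
        assert text.startswith("family\tSP\tTC\tpairs\tcols\n")
        assert "avg\t" in text

    def test_empty_core_family_excluded_from_mean(self):
        empty = CoreAnnotation({sid: () for sid in REF3.ids}, columns=4)
        rep = score_suite({
            "f1": (REF3, REF3, _full_core(REF3)),
            "f2": (REF3, REF3, empty),
        })
        assert rep.avg_tc == 1.0


class TestPairedTest:
    def test_identical_vectors(self):
        assert paired_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]) == 1.0

    def test_uniform_shift_eight_families(self):
        a = [0.5 + 0.01 * k for k in range(8)]
        b = [x + 0.02 for x in a]
        assert paired_test(b, a) == pytest.approx(2 / 2 ** 8)

    def test_antisymmetric(self):
        rng = np.random.default_rng(3)
        a = rng.random(8)
        b = rng.random(8)
        assert paired_test(a, b) == pytest.approx(paired_test(b, a))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = np.round(rng.random(7), 2)
            b = np.round(rng.random(7), 2)
            assert paired_test(a, b) == pytest.approx(
                exact_signed_rank_p(a - b))

    def test_matches_scipy_exact_when_no_ties(self):
        rng = np.random.default_rng(5)
        a = rng.random(10)
        b = a + rng.normal(0, 0.3, size=10)
        expected = stats.wilcoxon(a, b, alternative="two-sided",
                                  method="exact").pvalue
        assert paired_test(a, b) == pytest.approx(float(expected))

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            paired_test([1.0, 2.0], [1.0])
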