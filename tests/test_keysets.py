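"""Neighbourhoods, mismatch/gap key sets, reference formulas, expectations."""

from fractions import Fraction
from itertools import product

import pytest
from phcmap import gf4_code as g
from phcmap import keysets as K

AAAAA = (0, 0, 0, 0, 0)
AAAAG = (0, 0, 0, 0, 2)


class TestNeighborhood:
    def test_exact_sizes_l5(self):
        s = AAAAG
        assert len(K.neighborhood(s, 0)) == 1
        assert len(K.neighborhood(s, 1, exact=True)) == 15
        assert len(K.neighborhood(s, 2, exact=True)) == 90
        assert len(K.neighborhood(s, 2)) == 106

    def test_cumulative_size_l21(self):
        assert K.neighborhood_size(21, 2) == 1954
        s = (0,) * 21
        assert len(K.neighborhood(s, 1)) == 64

    def test_members_at_declared_distance(self):
        s = (1, 2, 3, 0, 1)
        for w in K.neighborhood(s, 2, exact=True):
            assert g.hamming(w, s) == 2

    def test_out_of_range_order(self):
        with pytest.raises(ValueError):
            K.neighborhood(AAAAA, 6)


class TestMismatchKeySets:
    def test_code_word_one_mismatch_is_single_key(self, code5):
        ks = K.key_set_mismatch(code5, AAAAA, 1)
        assert ks.keys == frozenset({AAAAA})

    def test_non_code_word_one_mismatch_is_seven_keys(self, code5):
        assert len(K.key_set_mismatch(code5, AAAAG, 1)) == 7

    def test_order_zero_is_decode(self, code5):
        assert K.key_set_mismatch(code5, AAAAG, 0).keys == frozenset({AAAAA})

    def test_l21_one_mismatch_sizes(self, code21):
        cw = code21.from_short_code(0)
        non = (1,) + (0,) * 20
        assert len(K.key_set_mismatch(code21, cw, 1)) == 1
        assert len(K.key_set_mismatch(code21, non, 1)) == 31

    def test_two_mismatch_sizes_constant_by_case(self, code5, all5):
        """Deduplicated |K2| depends only on code-word membership: 31 / 23."""
        sizes = {True: set(), False: set()}
        for s in all5:
            sizes[code5.is_code_word(s)].add(len(K.key_set_mismatch(code5, s, 2)))
        assert sizes[True] == {31}
        assert sizes[False] == {23}

    def test_one_mismatch_sizes_constant_by_case(self, code5, all5):
        sizes = {True: set(), False: set()}
        for s in all5:
            sizes[code5.is_code_word(s)].add(len(K.key_set_mismatch(code5, s, 1)))
        assert sizes[True] == {1}
        assert sizes[False] == {7}

    def test_completeness_exhaustive_l5(self, code5, all5):
        """Every word within the declared order decodes into the key set."""
        for s in all5:
            for n in (1, 2):
                ks = K.key_set_mismatch(code5, s, n)
                assert K.covers(code5, ks.keys, s, n)

    def test_keys_are_code_words_and_contain_centre(self, code5, all5):
        for s in all5[::11]:
            ks = K.key_set_mismatch(code5, s, 2)
            assert all(code5.is_code_word(k) for k in ks.keys)
            assert code5.decode(s) in ks.keys

    def test_k1_minimality_exhaustive(self, code5, all5):
        """Dropping any single key from K1 loses some 1-mismatch word."""
        for s in all5:
            keys = K.key_set_mismatch(code5, s, 1).keys
            for drop in keys:
                assert not K.covers(code5, keys - {drop}, s, 1)

    def test_length_mismatch_rejected(self, code5):
        with pytest.raises(g.CodeLengthError):
            K.key_set_mismatch(code5, (0,) * 21, 1)


class TestTypeTally:
    def test_published_tally_l5(self, code5, all5):
        """The four-type accounting books 31 (code word) / 27 = 7+8+12."""
        for s in all5[::7]:
            t = K.mismatch2_type_tally(code5, s)
            if code5.is_code_word(s):
                assert (t.k1, t.type3, t.type4, t.total) == (1, 30, 0, 31)
            else:
                assert (t.k1, t.type3, t.type4, t.total) == (7, 8, 12, 27)

    def test_published_tally_l21(self, code21):
        cw = code21.from_short_code(12345)
        non = (2,) + (0,) * 20
        assert K.mismatch2_type_tally(code21, cw).total == 631
        t = K.mismatch2_type_tally(code21, non)
        assert (t.k1, t.type3, t.type4, t.total) == (31, 520, 60, 611)

    def test_tally_bounds_dedup(self, code5, all5):
        # independent tallying can only over-count the deduplicated set
        for s in all5[::13]:
            assert K.mismatch2_type_tally(code5, s).total >= len(
                K.key_set_mismatch(code5, s, 2)
            )


class TestGapKeySets:
    def test_two_gap_example(self, code5):
        ks = K.key_set_gap(code5, K.parse_gapped("A-A-A"))
        assert len(ks) == 10
        assert AAAAA in ks.keys
        # the code word in S covers 7 of the 16 substitutions
        covered = [w for w in K.gap_substitutions(K.parse_gapped("A-A-A"))
                   if code5.decode(w) == AAAAA]
        assert len(covered) == 7

    def test_one_gap_sizes(self, code5):
        sizes = set()
        for gpos in range(5):
            for ctx in product(range(4), repeat=4):
                gw = list(ctx[:gpos]) + [K.GAP] + list(ctx[gpos:])
                subs = K.gap_substitutions(gw)
                size = len(K.key_set_gap(code5, tuple(gw)))
                if any(code5.is_code_word(w) for w in subs):
                    assert size == 1
                else:
                    assert size == 4
                sizes.add(size)
        assert sizes == {1, 4}

    def test_gap_completeness_exhaustive(self, code5):
        for ngaps in (1, 2):
            for gw in K._all_gapped(5, ngaps):
                keys = K.key_set_gap(code5, gw).keys
                for w in K.gap_substitutions(gw):
                    assert code5.decode(w) in keys

    def test_gapless_and_overgapped_rejected(self, code5):
        with pytest.raises(K.GapCountError):
            K.key_set_gap(code5, AAAAA)
        with pytest.raises(K.GapCountError):
            K.key_set_gap(code5, (K.GAP, K.GAP, K.GAP, 0, 0))

    def test_gapped_text_round_trip(self):
        assert K.gapped_to_text(K.parse_gapped("A-CG-")) == "A-CG-"


class TestReferenceFormulas:
    @pytest.mark.parametrize("s,n,expected", [
        (AAAAA, 1, (1, 15)),
        (AAAAG, 1, (1, 15, 42, 54)),
        (AAAAA, 2, (1, 15, 90, 210, 180)),
    ])
    def test_published_l5_cells(self, code5, s, n, expected):
        ks = K.key_set_mismatch(code5, s, n)
        assert K.reference_formula(code5, s, ks.keys).coeffs == expected

    def test_published_l21_k1_cell(self, code21):
        non = (1,) + (0,) * 20
        ks = K.key_set_mismatch(code21, non, 1)
        assert K.reference_formula(code21, non, ks.keys).coeffs == (1, 63, 210, 1710)

    def test_coefficient_sum_is_class_total(self, code5, code21):
        for code, s in [(code5, AAAAG), (code21, (1,) + (0,) * 20)]:
            for n in (1, 2):
                ks = K.key_set_mismatch(code, s, n)
                f = K.reference_formula(code, s, ks.keys)
                assert f.total == (3 * code.n + 1) * len(ks)

    def test_formula_cross_check_against_bruteforce(self, code5, all5):
        """Class-walk census equals a full 4^5 scan histogram."""
        decode_of = {w: code5.decode(w) for w in all5}
        for s in all5[::97]:
            keys = K.key_set_mismatch(code5, s, 2).keys
            f = K.reference_formula(code5, s, keys)
            brute = [0] * len(f.coeffs)
            for w in all5:
                if decode_of[w] in keys:
                    brute[g.hamming(w, s)] += 1
            assert tuple(brute) == f.coeffs

    def test_completeness_restated_per_distance(self, code5):
        f = K.reference_formula(code5, AAAAG, K.key_set_mismatch(code5, AAAAG, 2).keys)
        assert f.coeffs[0] >= 1 and f.coeffs[1] >= 15 and f.coeffs[2] >= 90

    def test_non_code_word_key_rejected(self, code5):
        with pytest.raises(g.NotACodeWordError):
            K.reference_formula(code5, AAAAA, [AAAAG])


class TestExpectations:
    def test_l5_rows(self, code5):
        r = K.expected_keys(code5, "1mm")
        assert r.expected_keys == Fraction(53, 8)  # 6.625
        assert r.expected_keys_2dp == "6.63" and float(r.expected_keys) == 6.625
        assert r.ratio_percent == "41.4%"
        r = K.expected_keys(code5, "2mm")
        assert r.expected_keys == Fraction(109, 4)  # 27.25, published accounting
        assert r.dedup == Fraction(47, 2)           # 23.5 deduplicated
        assert r.ratio_percent == "25.7%"

    def test_l21_mismatch_rows(self, code21):
        r = K.expected_keys(code21, "1mm", constancy_sample=5)
        assert r.expected_keys == Fraction(1954, 64)
        assert r.expected_keys_2dp == "30.53"
        assert r.ratio_percent == "47.7%"
        r = K.expected_keys(code21, "2mm", constancy_sample=3)
        assert r.expected_keys_2dp == "611.31"
        assert r.ratio_percent == "31.3%"

    def test_gap_rows(self, code5, code21):
        assert K.expected_keys(code5, "1gap").expected_keys == Fraction(13, 4)
        r = K.expected_keys(code5, "2gaps")
        assert r.expected_keys == 10
        assert r.ratio_percent == "62.5%"
        assert any("unreachable" in n for n in r.notes)
        r = K.expected_keys(code21, "1gap")
        assert r.expected_keys == Fraction(61, 16)
        assert r.expected_keys_2dp == "3.81"

    def test_l21_two_gap_discrepancy_flagged(self, code21):
        r = K.expected_keys(code21, "2gaps")
        assert r.expected_keys == Fraction(29, 2)  # the recomputed value
        text = K.render_table2([r])
        assert "13.87" in text and "14.50" in text

    def test_efficiency_headline(self, code5, code21):
        # expected keys stay below half the direct bill for all mismatch rows
        for code in (code5, code21):
            for cond in ("1mm", "2mm"):
                r = K.expected_keys(code, cond, constancy_sample=2)
                assert r.ratio < Fraction(1, 2)
                assert r.expected_keys <= r.n_words_direct

    def test_unknown_condition(self, code5):
        with pytest.raises(ValueError):
            K.expected_keys(code5, "3mm")


class TestTableRendering:
    def test_full_report_rows_and_annotations(self, code5, code21):
        rows = K.table2_report(code5, code21, constancy_sample=2)
        assert len(rows) == 8
        text = K.render_table2(rows)
        lines = text.strip().split("\n")
        assert len(lines) == 9
        assert "41.4%" in text and "47.7%" in text and "31.3%" in text
        # published figures are annotated, not silently replaced
        assert "30.25" in text and "3.84" in text and "13.87" in text
        assert "published non-code-word formula" in text
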