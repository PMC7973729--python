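"""The modified Needleman-Wunsch dynamic program and its traceback."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathalign import PenaltyScheme, mnw_distance, mnw_matrix, mnw_traceback

ALPHABET = "ABCDEFGHIJKLMNO"

pathway_strings = st.text(alphabet=ALPHABET, min_size=0, max_size=8)


def enumerate_alignment_min(a, b, catalog, pen):
    """Independent oracle: exhaustively accumulate step costs along every
    monotone alignment path and take the minimum."""
    best = [float("inf")]

    def walk(i, j, acc):
        if i == len(a) and j == len(b):
            best[0] = min(best[0], acc)
            return
        if i < len(a) and j < len(b):
            ca, cb = a[i], b[j]
            if ca == cb:
                walk(i + 1, j + 1, acc * pen.m + acc / (acc + catalog.weight(ca)))
            elif catalog.same_group(ca, cb):
                walk(i + 1, j + 1, acc + pen.s + abs(catalog.weight(ca) - catalog.weight(cb)))
            else:
                walk(i + 1, j + 1, acc + pen.ns + catalog.weight(ca) + catalog.weight(cb))
        if i < len(a):
            walk(i + 1, j, acc + pen.g + catalog.weight(a[i]))
        if j < len(b):
            walk(i, j + 1, acc + pen.g + catalog.weight(b[j]))

    walk(0, 0, 0.0)
    return best[0]


class TestWorkedExamples:
    """The C-vs-{DC,HC,DHC} matrices pin down every step type numerically."""

    def test_c_vs_dc_cells_and_increment(self, catalog, pen_min):
        m = mnw_matrix("C", "DC", catalog, pen_min)
        assert round(m.values[0, 1], 3) == 3.143  # gap over D: 2 + 1.143
        assert round(m.values[1, 2], 3) == 3.763
        assert round(m.distance - m.values[0, 1], 2) == 0.62

    def test_c_vs_hc_cells_and_increment(self, catalog, pen_min):
        m = mnw_matrix("C", "HC", catalog, pen_min)
        assert round(m.values[0, 1], 3) == 3.571
        assert round(m.distance, 3) == 4.221
        assert round(m.distance - m.values[0, 1], 2) == 0.65

    def test_c_vs_dhc_cells_and_increment(self, catalog, pen_min):
        m = mnw_matrix("C", "DHC", catalog, pen_min)
        assert round(m.values[0, 2], 3) == 6.714  # 3.143 + 2 + 1.571
        assert round(m.distance, 3) == 7.491
        assert round(m.distance - m.values[0, 2], 3) == 0.777

    def test_appended_character_costs_gap_plus_weight(self, catalog, pen_min):
        # matched prefix contributes 0, then one gap over K: 2 + 1.786
        d = mnw_distance("ABC", "ABCK", catalog, pen_min)
        assert d == pytest.approx(pen_min.g + catalog.weight("K"))

    def test_empty_vs_empty_is_1x1_zero(self, catalog, pen_min):
        m = mnw_matrix("", "", catalog, pen_min)
        assert m.values.shape == (1, 1) and m.distance == 0.0


class TestMatrixStructure:
    def test_boundary_rows_accumulate_weighted_gaps(self, catalog, pen_min):
        m = mnw_matrix("ABK", "DIJ", catalog, pen_min)
        col = m.values[:, 0]
        row = m.values[0, :]
        assert col[0] == 0.0
        assert np.all(np.diff(col) > 0) and np.all(np.diff(row) > 0)
        for i, c in enumerate("ABK", start=1):
            assert col[i] - col[i - 1] == pytest.approx(pen_min.g + catalog.weight(c))

    def test_interior_cells_are_min_of_predecessor_moves(self, catalog, pen_min):
        a, b = "ABKOC", "DIKJ"
        m = mnw_matrix(a, b, catalog, pen_min).values
        for i in range(1, len(a) + 1):
            for j in range(1, len(b) + 1):
                ca, cb = a[i - 1], b[j - 1]
                x = m[i - 1, j - 1]
                if ca == cb:
                    d = x * pen_min.m + x / (x + catalog.weight(ca))
                elif catalog.same_group(ca, cb):
                    d = x + pen_min.s + abs(catalog.weight(ca) - catalog.weight(cb))
                else:
                    d = x + pen_min.ns + catalog.weight(ca) + catalog.weight(cb)
                left = m[i - 1, j] + pen_min.g + catalog.weight(ca)
                top = m[i, j - 1] + pen_min.g + catalog.weight(cb)
                assert m[i, j] == pytest.approx(min(d, left, top))

    def test_unknown_code_rejected(self, catalog, pen_min):
        from pathalign import CatalogError

        with pytest.raises(CatalogError, match="unknown activity"):
            mnw_distance("ABZ", "ABC", catalog, pen_min)


class TestMetricProperties:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(x=pathway_strings)
    def test_distance_to_self_is_zero(self, x, catalog, pen_min):
        assert mnw_distance(x, x, catalog, pen_min) == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(a=pathway_strings, b=pathway_strings)
    def test_symmetry(self, a, b, catalog, pen_min):
        assert mnw_distance(a, b, catalog, pen_min) == pytest.approx(
            mnw_distance(b, a, catalog, pen_min), abs=1e-9
        )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(a=pathway_strings, b=pathway_strings)
    def test_zero_iff_equal(self, a, b, catalog, pen_min):
        d = mnw_distance(a, b, catalog, pen_min)
        assert (d == 0.0) == (a == b)
        assert d >= 0.0

    def test_matched_prefix_diagonal_is_zero(self, catalog, pen_min):
        """Cost accrues only from the first non-match of a shared prefix."""
        a, b = "ABKOC", "ABKL"
        m = mnw_matrix(a, b, catalog, pen_min).values
        for i in range(4):  # ABK shared, so diagonal cells 0..3 stay 0
            assert m[i, i] == 0.0
        assert m[4, 4] > 0.0

    def test_match_increment_decreases_with_weight(self, catalog, pen_min):
        """Matching a more important activity after the same context is cheaper."""
        x = 5.0
        incs = [x / (x + catalog.weight(c)) for c in sorted(ALPHABET, key=catalog.weight)]
        assert all(a > b for a, b in zip(incs, incs[1:]))

    def test_match_increment_increases_with_context(self, catalog, pen_min):
        """The later (costlier) the context, the larger the match increment."""
        inc = []
        for prefix in ("D", "H", "DH"):
            m = mnw_matrix("C", prefix + "C", catalog, pen_min)
            inc.append(m.distance - m.values[0, len(prefix)])
        assert inc[0] < inc[1] < inc[2]
        assert all(0 < i < 1 for i in inc)

    def test_gap_increment_increases_with_weight(self, catalog, pen_min):
        gaps = [mnw_distance("", c, catalog, pen_min) for c in sorted(ALPHABET, key=catalog.weight)]
        assert all(a < b for a, b in zip(gaps, gaps[1:]))

    def test_swap_increment_increases_with_rank_separation(self, catalog, pen_min):
        """Within group {K, L, N}: swapping closer-ranked activities is cheaper."""
        d_kl = mnw_distance("K", "L", catalog, pen_min)
        d_kn = mnw_distance("K", "N", catalog, pen_min)
        assert d_kl < d_kn
        assert d_kl == pytest.approx(pen_min.s + abs(catalog.weight("K") - catalog.weight("L")))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        g=st.floats(min_value=1.01, max_value=10),
        s_frac=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_step_cost_ordering_under_valid_schemes(self, g, s_frac, catalog):
        """Per-step costs order match < swap < gap < no-swap for any
        guideline-compliant scheme."""
        s = 1.01 + s_frac * (g - 1.01)
        pen = PenaltyScheme.unchecked(m=1, s=s, g=g, ns=2 * g + 1)
        w_lo, w_hi = 1.0, 2.0
        match_hi = 1.0  # x/(x+w) < 1 always
        swap_lo, swap_hi = s, s + (w_hi - w_lo)
        gap_lo, gap_hi = g + w_lo, g + w_hi
        ns_lo = pen.ns + 2 * w_lo
        assert match_hi <= swap_lo
        assert swap_hi <= s + 1 <= gap_lo
        assert gap_hi < ns_lo


class TestEnumerationOracle:
    def test_dp_equals_exhaustive_path_enumeration(self, small_catalog, pen_min):
        """DP minimum equals brute-force minimisation over all monotone
        alignment paths (all string pairs up to length 3 over 5 letters)."""
        letters = small_catalog.codes
        strings = [""] + [
            "".join(t) for L in (1, 2, 3) for t in itertools.product(letters, repeat=L)
        ]
        for a in strings:
            for b in strings:
                dp = mnw_distance(a, b, small_catalog, pen_min)
                oracle = enumerate_alignment_min(a, b, small_catalog, pen_min)
                assert dp == pytest.approx(oracle, abs=1e-9), (a, b)


class TestTraceback:
    def test_identity_alignment_is_all_matches(self, catalog, pen_min):
        m = mnw_matrix("ABC", "ABC", catalog, pen_min)
        al = mnw_traceback(m, catalog, pen_min)
        assert [s.kind for s in al.steps] == ["match"] * 3
        assert al.distance == 0.0

    def test_gap_then_match(self, catalog, pen_min):
        m = mnw_matrix("C", "DC", catalog, pen_min)
        al = mnw_traceback(m, catalog, pen_min)
        assert [(s.kind, s.code_a, s.code_b) for s in al.steps] == [
            ("gap_in_a", None, "D"),
            ("match", "C", "C"),
        ]
        assert al.as_strings() == ("-C", "DC")

    def test_prefers_gapping_over_swapping_when_cheaper(self, catalog, pen_min):
        """Aligning ABKOGNCH with ABC keeps B matched to B (gapping K, O, G,
        N) instead of swapping B with O, despite B and O sharing a group."""
        m = mnw_matrix("ABKOGNCH", "ABC", catalog, pen_min)
        al = mnw_traceback(m, catalog, pen_min)
        pairs = [(s.code_a, s.code_b) for s in al.steps if s.kind in ("match", "swap")]
        assert ("A", "A") in pairs and ("B", "B") in pairs and ("C", "C") in pairs
        assert not any(s.kind == "swap" for s in al.steps)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(a=pathway_strings, b=pathway_strings)
    def test_replaying_step_costs_reproduces_distance(self, a, b, catalog, pen_min):
        m = mnw_matrix(a, b, catalog, pen_min)
        al = mnw_traceback(m, catalog, pen_min)
        assert sum(s.cost for s in al.steps) == pytest.approx(m.distance, abs=1e-9)
        row_a, row_b = al.as_strings()
        assert row_a.replace("-", "") == a and row_b.replace("-", "") == b
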