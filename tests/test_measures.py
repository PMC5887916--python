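"""Anisotropy measures: orientation bands, cardinality, separation, symmetry."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from scriptaniso.measures import (
    Undefined,
    cardinal_band_fraction,
    chance_purity,
    classify_orientation,
    detect_mirror_symmetry,
    letter_cardinality,
    letter_is_pure,
    letter_symmetry_class,
    orientation_breakdown,
    script_cardinality,
    separation_index,
    symmetric_letter_proportion,
    vertical_symmetry_dominance,
)
from scriptaniso.model import GlyphGeometry, LetterCoding


def L(h, v, o, sym="none", lid="x"):
    return LetterCoding(lid, h, v, o, sym)


class TestOrientation:
    @pytest.mark.parametrize(
        "angle,expected",
        [
            (0.0, "horizontal"),
            (179.0, "horizontal"),
            (90.0, "vertical"),
            (85.0, "vertical"),
            (45.0, "oblique"),
            (10.0, "oblique"),  # strict "less than" boundary
            (80.0, "oblique"),
            (100.0, "oblique"),
            (-5.0, "horizontal"),  # reduced modulo 180
            (190.0, "oblique"),  # 190 mod 180 = 10, on the boundary
            (360.0, "horizontal"),
        ],
    )
    def test_band_classification(self, angle, expected):
        assert classify_orientation(angle) == expected

    @given(st.floats(min_value=-1e4, max_value=1e4, allow_nan=False))
    def test_partition_is_exhaustive_and_exclusive(self, angle):
        assert classify_orientation(angle) in ("horizontal", "vertical", "oblique")

    def test_fine_grid_cardinal_fraction_approaches_band_measure(self):
        grid = np.arange(0.0, 180.0, 0.01)
        frac = np.mean([classify_orientation(a) != "oblique" for a in grid])
        assert abs(frac - 80.0 / 360.0) < 1e-3

    def test_band_fraction_values(self):
        assert cardinal_band_fraction() == pytest.approx(80.0 / 360.0, abs=0)
        assert cardinal_band_fraction(0.0) == 0.0
        assert cardinal_band_fraction(45.0) == 1.0


class TestCardinality:
    @pytest.mark.parametrize(
        "letter,expected",
        [(L(3, 1, 0), 1.0), (L(0, 0, 2), 0.0), (L(1, 0, 1), 0.5)],
    )
    def test_letter_cardinality(self, letter, expected):
        assert letter_cardinality(letter) == expected

    def test_curve_only_letter_is_undefined(self):
        assert isinstance(letter_cardinality(L(0, 0, 0)), Undefined)

    def test_script_cardinality_modes_diverge(self):
        letters = [L(2, 0, 0), L(0, 0, 1)]
        assert script_cardinality(letters, "letter_mean") == pytest.approx(0.5)
        assert script_cardinality(letters, "pooled") == pytest.approx(2 / 3)

    def test_script_cardinality_undefined_without_strokes(self):
        assert isinstance(script_cardinality([L(0, 0, 0)]), Undefined)

    def test_orientation_breakdown_sums_to_one(self):
        shares = orientation_breakdown([L(1, 1, 2)])
        assert shares == pytest.approx((0.25, 0.25, 0.5))
        assert orientation_breakdown([L(2, 0, 0), L(1, 0, 0)]) == pytest.approx((1, 0, 0))

    def test_breakdown_recovers_generating_probabilities(self, rng):
        # 10^4 single-stroke letters with orientation probs (0.3, 0.3, 0.4)
        draws = rng.choice(3, size=10_000, p=[0.3, 0.3, 0.4])
        letters = [L(int(d == 0), int(d == 1), int(d == 2)) for d in draws]
        shares = orientation_breakdown(letters, "pooled")
        se = 3 * np.sqrt(0.3 * 0.7 / 10_000)
        assert abs(shares[0] - 0.3) < se and abs(shares[1] - 0.3) < se


class TestChancePurity:
    def test_half_and_half_two_lines(self):
        # enumeration: of the 4 equiprobable allocations, 2 are pure
        assert chance_purity(0.5, 2) == pytest.approx(0.5)

    def test_single_line_always_pure(self):
        for c in (0.0, 0.3, 1.0):
            assert chance_purity(c, 1) == 1.0

    def test_study_scale_value(self):
        assert chance_purity(0.61, 3) == pytest.approx(0.2863, abs=5e-5)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            chance_purity(0.5, 0)

    @given(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        st.integers(min_value=1, max_value=30),
    )
    def test_symmetric_in_c(self, c, n):
        assert chance_purity(c, n) == pytest.approx(chance_purity(1.0 - c, n), abs=1e-12)

    @given(
        st.floats(min_value=0.05, max_value=0.95, allow_nan=False),
        st.integers(min_value=1, max_value=29),
    )
    def test_strictly_decreasing_in_n(self, c, n):
        assert chance_purity(c, n + 1) < chance_purity(c, n)


class TestPurityAndSeparation:
    @pytest.mark.parametrize(
        "letter,expected",
        [(L(3, 1, 0), True), (L(0, 0, 3), True), (L(1, 1, 2), False)],
    )
    def test_letter_is_pure(self, letter, expected):
        assert letter_is_pure(letter) is expected

    def test_all_pure_with_even_split_gives_plus_half(self):
        # c = 0.5, every letter n=2 pure: chance 0.5 each, observed 1.0
        letters = [L(2, 0, 0), L(0, 0, 2)] * 3
        assert separation_index(letters) == pytest.approx(0.5)

    def test_single_line_script_is_undefined(self):
        # the Thaana-style exclusion: no letter has more than one straight line
        out = separation_index([L(1, 0, 0), L(0, 0, 1)])
        assert isinstance(out, Undefined) and "multi-line" in out.reason

    def test_relabeling_invariance(self, rng):
        letters = [
            L(int(rng.integers(3)), int(rng.integers(3)), int(rng.integers(3)), lid=f"l{i}")
            for i in range(30)
        ]
        letters = [l for l in letters if l.n_strokes > 0]
        shuffled = list(letters)
        rng.shuffle(shuffled)
        assert separation_index(letters) == pytest.approx(separation_index(shuffled))


class TestMirrorSymmetry:
    A_GLYPH = GlyphGeometry("A", ((-1, 0, 0, 2), (0, 2, 1, 0), (-0.5, 1, 0.5, 1)))
    SQUARE = GlyphGeometry("sq", ((0, 0, 1, 0), (1, 0, 1, 1), (1, 1, 0, 1), (0, 1, 0, 0)))
    L_GLYPH = GlyphGeometry("L", ((0, 0, 0, 2), (0, 0, 1, 0)))

    def test_a_like_glyph_vertical_only(self):
        assert detect_mirror_symmetry(self.A_GLYPH, "vertical")
        assert not detect_mirror_symmetry(self.A_GLYPH, "horizontal")

    def test_unit_square_both(self):
        assert detect_mirror_symmetry(self.SQUARE, "vertical")
        assert detect_mirror_symmetry(self.SQUARE, "horizontal")

    def test_l_like_glyph_neither(self):
        assert not detect_mirror_symmetry(self.L_GLYPH, "vertical")
        assert not detect_mirror_symmetry(self.L_GLYPH, "horizontal")

    def test_empty_glyph_raises(self):
        with pytest.raises(ValueError):
            detect_mirror_symmetry(GlyphGeometry("o", ()), "vertical")

    @pytest.mark.parametrize("dx,dy,scale", [(3.0, -2.0, 1.0), (0.0, 0.0, 7.5), (-1.0, 4.0, 0.25)])
    def test_invariant_to_translation_and_scaling(self, dx, dy, scale):
        for glyph in (self.A_GLYPH, self.SQUARE, self.L_GLYPH):
            moved = GlyphGeometry(
                glyph.letter_id,
                tuple(
                    (scale * x1 + dx, scale * y1 + dy, scale * x2 + dx, scale * y2 + dy)
                    for (x1, y1, x2, y2) in glyph.segments
                ),
            )
            for axis in ("vertical", "horizontal"):
                assert detect_mirror_symmetry(moved, axis) == detect_mirror_symmetry(glyph, axis)

    def test_invariant_to_segment_order_and_endpoint_swap(self):
        for glyph in (self.A_GLYPH, self.SQUARE):
            perm = GlyphGeometry(
                glyph.letter_id,
                tuple((x2, y2, x1, y1) for (x1, y1, x2, y2) in reversed(glyph.segments)),
            )
            for axis in ("vertical", "horizontal"):
                assert detect_mirror_symmetry(perm, axis) == detect_mirror_symmetry(glyph, axis)

    def test_symmetry_class_exemplars(self):
        t_glyph = GlyphGeometry("T", ((0, 4, 2, 4), (1, 0, 1, 4)))
        e_glyph = GlyphGeometry("E", ((0, 0, 0, 4), (0, 4, 2, 4), (0, 2, 1.5, 2), (0, 0, 2, 0)))
        assert letter_symmetry_class(self.SQUARE) == "both"
        assert letter_symmetry_class(t_glyph) == "vertical"
        assert letter_symmetry_class(e_glyph) == "horizontal"


class TestSymmetryPrevalence:
    def test_three_vertical_one_horizontal(self):
        letters = [L(1, 0, 0, s) for s in ("vertical", "vertical", "vertical", "horizontal")]
        assert vertical_symmetry_dominance(letters) == pytest.approx(0.75)

    def test_cutoff_is_strictly_more_than_three(self):
        letters = [L(1, 0, 0, s) for s in ("vertical", "vertical", "horizontal")]
        assert isinstance(vertical_symmetry_dominance(letters), Undefined)

    def test_unchanged_by_adding_asymmetric_letters(self):
        base = [L(1, 0, 0, s) for s in ("vertical",) * 3 + ("horizontal",) * 2]
        padded = base + [L(1, 1, 1, "none")] * 10
        assert vertical_symmetry_dominance(padded) == vertical_symmetry_dominance(base)

    def test_include_both_counts_half(self):
        letters = [L(1, 0, 0, s) for s in ("vertical",) * 2 + ("horizontal",) * 2 + ("both",) * 2]
        assert vertical_symmetry_dominance(letters, include_both=True) == pytest.approx(
            (2 + 2) / (2 + 2 + 4)
        )

    def test_latin_fixture_hand_count(self, latin_glyphs, latin_expected):
        from scriptaniso.measures import derive_coding

        letters = [derive_coding(g) for g in latin_glyphs]
        # hand count on the stored oracle: 6 vertical, 4 horizontal
        assert vertical_symmetry_dominance(letters) == pytest.approx(6 / 10)
        assert symmetric_letter_proportion(letters) == pytest.approx(16 / 26)

    def test_symmetric_proportion_examples(self):
        assert symmetric_letter_proportion([L(1, 0, 0, "none")] * 4) == 0.0
        letters = [L(1, 0, 0, s) for s in ("vertical", "none", "horizontal", "none")]
        assert symmetric_letter_proportion(letters) == 0.5

    def test_symmetric_proportion_recovers_generating_rate(self, rng):
        flips = rng.random(1000) < 0.4
        letters = [L(1, 0, 0, "vertical" if f else "none") for f in flips]
        se = 3 * np.sqrt(0.4 * 0.6 / 1000)
        assert abs(symmetric_letter_proportion(letters) - 0.4) < se
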