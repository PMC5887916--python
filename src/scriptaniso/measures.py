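"""Orientation-anisotropy measures for letter strokes.

Implements the three script-level legibility measures:

* **cardinality** — the mean proportion of a letter's straight lines that lie
  within a cardinal band (strictly less than ``half_width`` degrees, default
  10, from horizontal or vertical), averaged over letters;
* **separation index** — the observed proportion of "pure" letters (all lines
  cardinal or all oblique) minus the mean chance probability of purity under
  independent random allocation of cardinal/oblique identity to each line;
* **vertical-symmetry dominance** — among letters mirror-symmetric about
  exactly one axis, the share symmetric about the vertical axis, defined only
  for scripts with more than ``min_usable`` such letters.

Plus the geometric bridges: an orientation classifier for segments and a
mirror-symmetry detector, so that stroke codings can be derived from raw
segment geometry instead of hand coding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import GlyphGeometry, LetterCoding

CardinalityMode = Literal["letter_mean", "pooled"]

#: Angular half-width of the cardinal bands, degrees (strict inequality).
DEFAULT_HALF_WIDTH = 10.0

#: Relative symmetry tolerance, as a fraction of the bounding-box diagonal.
DEFAULT_SYMMETRY_TOL = 0.02


@dataclass(frozen=True)
class Undefined:
    """Marker for a measure that cannot be computed, with the reason why."""

    reason: str

    def __bool__(self) -> bool:
        return False


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def classify_orientation(angle_deg: float, half_width: float = DEFAULT_HALF_WIDTH) -> str:
    """Classify an undirected stroke angle as horizontal, vertical or oblique.

    Angles are reduced modulo 180 degrees; a stroke is horizontal iff its
    reduced angle is strictly within ``half_width`` of 0/180, vertical iff
    strictly within ``half_width`` of 90, oblique otherwise.
    """
    a = float(angle_deg) % 180.0
    if min(a, 180.0 - a) < half_width:
        return "horizontal"
    if abs(a - 90.0) < half_width:
        return "vertical"
    return "oblique"


def segment_angle_deg(x1: float, y1: float, x2: float, y2: float) -> float:
    """Undirected angle of a segment in degrees within [0, 180)."""
    return math.degrees(math.atan2(y2 - y1, x2 - x1)) % 180.0


def cardinal_band_fraction(half_width: float = DEFAULT_HALF_WIDTH) -> float:
    """Fraction of the full 360-degree compass covered by the cardinal bands.

    Four bands of width ``2 * half_width`` (around 0, 90, 180 and 270
    degrees); at the default 10-degree half-width this is 80/360, the chance
    level against which script cardinality is judged.
    """
    if not 0.0 <= half_width <= 45.0:
        raise ValueError("half_width must be in [0, 45] degrees")
    return (8.0 * half_width) / 360.0


# ---------------------------------------------------------------------------
# cardinality
# ---------------------------------------------------------------------------

def letter_cardinality(coding: LetterCoding) -> float | Undefined:
    """Proportion of a letter's straight lines that are cardinal.

    Undefined for letters without straight lines (curve-only letters).
    """
    n = coding.n_strokes
    if n == 0:
        return Undefined("no straight lines")
    return coding.n_cardinal / n


def script_cardinality(
    letters: Sequence[LetterCoding], mode: CardinalityMode = "letter_mean"
) -> float | Undefined:
    """Script-level cardinality ``c``.

    ``letter_mean`` (default) is the unweighted mean of per-letter cardinality
    over letters with at least one straight line; ``pooled`` is the ratio of
    cardinal lines to all straight lines in the script.
    """
    usable = [l for l in letters if l.n_strokes > 0]
    if not usable:
        return Undefined("no letter has a straight line")
    if mode == "letter_mean":
        return float(np.mean([l.n_cardinal / l.n_strokes for l in usable]))
    if mode == "pooled":
        total = sum(l.n_strokes for l in usable)
        return sum(l.n_cardinal for l in usable) / total
    raise ValueError(f"unknown cardinality mode {mode!r}")


def orientation_breakdown(
    letters: Sequence[LetterCoding], mode: CardinalityMode = "letter_mean"
) -> tuple[float, float, float]:
    """Shares of horizontal, vertical and oblique lines, summing to 1."""
    usable = [l for l in letters if l.n_strokes > 0]
    if not usable:
        raise ValueError("orientation breakdown needs at least one straight line")
    if mode == "letter_mean":
        shares = np.array(
            [
                [l.n_horizontal / l.n_strokes, l.n_vertical / l.n_strokes, l.n_oblique / l.n_strokes]
                for l in usable
            ]
        ).mean(axis=0)
    elif mode == "pooled":
        total = sum(l.n_strokes for l in usable)
        shares = np.array(
            [
                sum(l.n_horizontal for l in usable) / total,
                sum(l.n_vertical for l in usable) / total,
                sum(l.n_oblique for l in usable) / total,
            ]
        )
    else:
        raise ValueError(f"unknown cardinality mode {mode!r}")
    return (float(shares[0]), float(shares[1]), float(shares[2]))


# ---------------------------------------------------------------------------
# separation
# ---------------------------------------------------------------------------

def chance_purity(c: float, n: int) -> float:
    """Chance probability that a letter with ``n`` straight lines is pure.

    Under independent random allocation of cardinal (probability ``c``) or
    oblique identity to each of the letter's ``n`` lines, the letter is 100%
    cardinal with probability c^n and 100% oblique with probability (1-c)^n.
    """
    if not (isinstance(n, (int, np.integer)) and not isinstance(n, bool)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"c must lie in [0, 1], got {c!r}")
    return c**n + (1.0 - c) ** n


def letter_is_pure(coding: LetterCoding) -> bool | Undefined:
    """True iff all the letter's straight lines are cardinal, or all oblique."""
    if coding.n_strokes == 0:
        return Undefined("no straight lines")
    return coding.n_oblique == 0 or coding.n_cardinal == 0


def separation_index(
    letters: Sequence[LetterCoding], mode: CardinalityMode = "letter_mean"
) -> float | Undefined:
    """Observed purity minus mean chance purity, in [-1, 1].

    Positive values mean pure letters (like E or W) are more common than
    independent allocation of the script's cardinality would predict. The
    measure is undefined for scripts in which no letter has more than one
    straight line (every letter is then trivially pure).
    """
    usable = [l for l in letters if l.n_strokes > 0]
    if not usable:
        return Undefined("no letter has a straight line")
    if not any(l.n_strokes >= 2 for l in usable):
        return Undefined("no multi-line letters")
    c = script_cardinality(letters, mode)
    observed = float(np.mean([1.0 if letter_is_pure(l) else 0.0 for l in usable]))
    expected = float(np.mean([chance_purity(c, l.n_strokes) for l in usable]))
    return observed - expected


# ---------------------------------------------------------------------------
# mirror symmetry
# ---------------------------------------------------------------------------

def _segment_array(glyph: GlyphGeometry) -> np.ndarray:
    return np.asarray(glyph.segments, dtype=float).reshape(-1, 4)


def detect_mirror_symmetry(
    glyph: GlyphGeometry,
    axis: Literal["vertical", "horizontal"],
    tolerance: float = DEFAULT_SYMMETRY_TOL,
) -> bool:
    """Test mirror symmetry of a glyph about an axis through its bbox center.

    Segments are reflected about the vertical (x -> 2*cx - x) or horizontal
    (y -> 2*cy - y) axis and matched one-to-one against the originals, each
    segment treated as an unordered endpoint pair. The glyph is symmetric iff
    a perfect matching exists with every endpoint displaced by less than
    ``tolerance`` times the bounding-box diagonal.
    """
    segs = _segment_array(glyph)
    if segs.shape[0] == 0:
        raise ValueError(f"empty glyph {glyph.letter_id!r} has no symmetry axis")
    pts = segs.reshape(-1, 2)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    diag = float(np.hypot(*(hi - lo)))
    if diag == 0.0:  # cannot happen: zero-length segments are rejected upstream
        raise ValueError("degenerate glyph with zero bounding box")
    center = (lo + hi) / 2.0

    reflected = segs.copy()
    if axis == "vertical":
        reflected[:, [0, 2]] = 2.0 * center[0] - reflected[:, [0, 2]]
    elif axis == "horizontal":
        reflected[:, [1, 3]] = 2.0 * center[1] - reflected[:, [1, 3]]
    else:
        raise ValueError(f"axis must be 'vertical' or 'horizontal', got {axis!r}")

    # pairwise segment distance: best over the two endpoint pairings
    a1, a2 = segs[:, None, 0:2], segs[:, None, 2:4]
    b1, b2 = reflected[None, :, 0:2], reflected[None, :, 2:4]
    direct = np.maximum(
        np.linalg.norm(a1 - b1, axis=-1), np.linalg.norm(a2 - b2, axis=-1)
    )
    swapped = np.maximum(
        np.linalg.norm(a1 - b2, axis=-1), np.linalg.norm(a2 - b1, axis=-1)
    )
    dist = np.minimum(direct, swapped)
    rows, cols = linear_sum_assignment(dist)
    return bool(np.all(dist[rows, cols] < tolerance * diag))


def letter_symmetry_class(
    glyph: GlyphGeometry, tolerance: float = DEFAULT_SYMMETRY_TOL
) -> str:
    """Mirror-symmetry class of a glyph: none, vertical, horizontal or both.

    Only the two mirror axes are tested; a glyph with rotational symmetry but
    no mirror symmetry (like Z or N) is classed ``none``.
    """
    v = detect_mirror_symmetry(glyph, "vertical", tolerance)
    h = detect_mirror_symmetry(glyph, "horizontal", tolerance)
    if v and h:
        return "both"
    if v:
        return "vertical"
    if h:
        return "horizontal"
    return "none"


def derive_coding(
    glyph: GlyphGeometry,
    tolerance: float = DEFAULT_SYMMETRY_TOL,
    half_width: float = DEFAULT_HALF_WIDTH,
) -> LetterCoding:
    """Derive a stroke coding from segment geometry.

    Each segment is classified by its undirected angle; the symmetry class
    comes from the geometric mirror detector. An empty glyph codes to all-zero
    counts with symmetry ``none``.
    """
    counts = {"horizontal": 0, "vertical": 0, "oblique": 0}
    for (x1, y1, x2, y2) in glyph.segments:
        counts[classify_orientation(segment_angle_deg(x1, y1, x2, y2), half_width)] += 1
    symmetry = "none" if not glyph.segments else letter_symmetry_class(glyph, tolerance)
    return LetterCoding(
        letter_id=glyph.letter_id,
        n_horizontal=counts["horizontal"],
        n_vertical=counts["vertical"],
        n_oblique=counts["oblique"],
        symmetry=symmetry,
    )


# ---------------------------------------------------------------------------
# symmetry prevalence
# ---------------------------------------------------------------------------

def vertical_symmetry_dominance(
    letters: Sequence[LetterCoding],
    min_usable: int = 3,
    include_both: bool = False,
) -> float | Undefined:
    """Share of vertical symmetry among single-axis mirror-symmetric letters.

    With ``include_both`` the letters symmetric about both axes enter the
    ratio as half-vertical half-horizontal. A script needs strictly more than
    ``min_usable`` usable letters to get a score.
    """
    v = sum(1 for l in letters if l.symmetry == "vertical")
    h = sum(1 for l in letters if l.symmetry == "horizontal")
    b = sum(1 for l in letters if l.symmetry == "both")
    usable = v + h + (b if include_both else 0)
    if usable <= min_usable:
        return Undefined(f"only {usable} usable letters (need > {min_usable})")
    if include_both:
        return (v + b) / (v + h + 2 * b)
    return v / (v + h)


def count_usable_symmetry(letters: Sequence[LetterCoding], include_both: bool = False) -> int:
    v = sum(1 for l in letters if l.symmetry == "vertical")
    h = sum(1 for l in letters if l.symmetry == "horizontal")
    b = sum(1 for l in letters if l.symmetry == "both")
    return v + h + (b if include_both else 0)


def symmetric_letter_proportion(letters: Sequence[LetterCoding]) -> float:
    """Proportion of letters mirror-symmetric about either axis (or both)."""
    if not letters:
        raise ValueError("symmetric_letter_proportion needs at least one letter")
    k = sum(1 for l in letters if l.symmetry in ("vertical", "horizontal", "both"))
    return k / len(letters)


# ---------------------------------------------------------------------------
# script-level record
# ---------------------------------------------------------------------------

def compute_measures(
    script_code: str,
    letters: Sequence[LetterCoding],
    mode: CardinalityMode = "letter_mean",
    min_usable: int = 3,
    include_both: bool = False,
):
    """Compute all measures for one script, returning a MeasureRecord."""
    from .model import MeasureRecord

    rec = MeasureRecord(script_code=script_code, n_letters=len(letters))
    usable = [l for l in letters if l.n_strokes > 0]

    card = script_cardinality(letters, mode)
    if isinstance(card, Undefined):
        rec.cardinality_reason = card.reason
    else:
        rec.cardinality = card
        rec.cardinality_n = len(usable)

    sep = separation_index(letters, mode)
    if isinstance(sep, Undefined):
        rec.separation_reason = sep.reason
    else:
        rec.separation_index = sep
        rec.separation_n = len(usable)

    vsym = vertical_symmetry_dominance(letters, min_usable, include_both)
    if isinstance(vsym, Undefined):
        rec.vsym_reason = vsym.reason
    else:
        rec.vsym_dominance = vsym
        rec.vsym_n = count_usable_symmetry(letters, include_both)

    if letters:
        rec.symmetric_proportion = symmetric_letter_proportion(letters)
    return rec


def measures_for_collection(
    collection,
    mode: CardinalityMode = "letter_mean",
    min_usable: int = 3,
    include_both: bool = False,
    tolerance: float = DEFAULT_SYMMETRY_TOL,
):
    """MeasureRecords for every script in a collection.

    Scripts coded only geometrically get their codings derived from glyphs.
    """
    records = []
    for script in collection:
        letters = list(script.letters)
        if not letters and script.glyphs:
            letters = [derive_coding(g, tolerance) for g in script.glyphs]
        records.append(
            compute_measures(script.script_code, letters, mode, min_usable, include_both)
        )
    return records
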