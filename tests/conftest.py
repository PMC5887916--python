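"""Shared fixtures: a synthetic geometric Latin-capitals alphabet.

The glyphs are straight-segment skeletons (synthetic, designed for these
tests, not traced from any font): curve strokes are omitted, so curve-only
letters (C, O, S) have empty glyphs. ``LATIN_EXPECTED`` is the hand-derived
oracle for this exact geometry — orientation counts per the <10-degree
cardinal bands and mirror-symmetry classes of the segment sets — worked out
once by hand and frozen here.
"""

import numpy as np
import pytest
from hypothesis import settings

from scriptaniso.model import GlyphGeometry

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

# segment skeletons; x rightward, y upward
LATIN_SEGMENTS = {
    "A": [(0, 0, 1, 4), (2, 0, 1, 4), (0.5, 2, 1.5, 2)],
    "B": [(0, 0, 0, 4), (0, 4, 1, 4), (0, 2, 1, 2), (0, 0, 1, 0)],
    "C": [],
    "D": [(0, 0, 0, 4), (0, 4, 1, 4), (0, 0, 1, 0)],
    "E": [(0, 0, 0, 4), (0, 4, 2, 4), (0, 2, 1.5, 2), (0, 0, 2, 0)],
    "F": [(0, 0, 0, 4), (0, 4, 2, 4), (0, 2, 1.5, 2)],
    "G": [(1, 2, 2, 2)],
    "H": [(0, 0, 0, 4), (2, 0, 2, 4), (0, 2, 2, 2)],
    "I": [(0, 0, 0, 4)],
    "J": [(1, 1, 1, 4)],
    "K": [(0, 0, 0, 4), (0, 2, 1.5, 4), (0, 2, 1.5, 0)],
    "L": [(0, 0, 0, 4), (0, 0, 2, 0)],
    "M": [(0, 0, 0, 4), (3, 0, 3, 4), (0, 4, 1.5, 1.5), (3, 4, 1.5, 1.5)],
    "N": [(0, 0, 0, 4), (2, 0, 2, 4), (0, 4, 2, 0)],
    "O": [],
    "P": [(0, 0, 0, 4), (0, 4, 1, 4), (0, 2, 1, 2)],
    "Q": [(1.5, 0.5, 2.5, -0.5)],
    "R": [(0, 0, 0, 4), (0, 4, 1, 4), (0, 2, 1, 2), (0.5, 2, 2, 0)],
    "S": [],
    "T": [(0, 4, 2, 4), (1, 0, 1, 4)],
    "U": [(0, 1, 0, 4), (2, 1, 2, 4)],
    "V": [(0, 4, 1, 0), (2, 4, 1, 0)],
    "W": [(0, 4, 0.75, 0), (0.75, 0, 1.5, 3), (1.5, 3, 2.25, 0), (2.25, 0, 3, 4)],
    "X": [(0, 0, 2, 4), (0, 4, 2, 0)],
    "Y": [(0, 4, 1, 2), (2, 4, 1, 2), (1, 0, 1, 2)],
    "Z": [(0, 4, 2, 4), (2, 4, 0, 0), (0, 0, 2, 0)],
}

# hand-derived oracle: (n_horizontal, n_vertical, n_oblique, symmetry)
LATIN_EXPECTED = {
    "A": (1, 0, 2, "vertical"),
    "B": (3, 1, 0, "horizontal"),
    "C": (0, 0, 0, "none"),
    "D": (2, 1, 0, "horizontal"),
    "E": (3, 1, 0, "horizontal"),
    "F": (2, 1, 0, "none"),
    "G": (1, 0, 0, "both"),
    "H": (1, 2, 0, "both"),
    "I": (0, 1, 0, "both"),
    "J": (0, 1, 0, "both"),
    "K": (0, 1, 2, "horizontal"),
    "L": (1, 1, 0, "none"),
    "M": (0, 2, 2, "vertical"),
    "N": (0, 2, 1, "none"),
    "O": (0, 0, 0, "none"),
    "P": (2, 1, 0, "none"),
    "Q": (0, 0, 1, "none"),
    "R": (2, 1, 1, "none"),
    "S": (0, 0, 0, "none"),
    "T": (1, 1, 0, "vertical"),
    "U": (0, 2, 0, "both"),
    "V": (0, 0, 2, "vertical"),
    "W": (0, 0, 4, "vertical"),
    "X": (0, 0, 2, "both"),
    "Y": (0, 1, 2, "vertical"),
    "Z": (2, 0, 1, "none"),
}


@pytest.fixture(scope="session")
def latin_glyphs() -> list[GlyphGeometry]:
    return [
        GlyphGeometry(letter_id=letter, segments=tuple(segs))
        for letter, segs in LATIN_SEGMENTS.items()
    ]


@pytest.fixture(scope="session")
def latin_expected() -> dict:
    return LATIN_EXPECTED


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
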