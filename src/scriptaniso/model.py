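"""Domain types for scripts, letters, lineages and per-script measures.

A *script* is a writing system (identified by its ISO 15924 code or a free
label); its *letters* are coded either as straight-line stroke counts
(:class:`LetterCoding`) or as raw segment geometry (:class:`GlyphGeometry`)
from which a coding can be derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

SYMMETRY_CLASSES = ("none", "vertical", "horizontal", "both", "other")
STATUS_VALUES = ("live", "extinct")
DIRECTION_VALUES = ("ltr", "rtl", "ttb", "other")


@dataclass(frozen=True)
class LetterCoding:
    """Straight-line stroke counts and mirror-symmetry class of one letter.

    ``n_strokes`` (the letter's total number of straight lines) is the sum of
    the three orientation counts; curve strokes are not represented, so a
    curve-only letter legitimately has all counts zero.
    """

    letter_id: str
    n_horizontal: int
    n_vertical: int
    n_oblique: int
    symmetry: str = "none"

    def __post_init__(self) -> None:
        for name in ("n_horizontal", "n_vertical", "n_oblique"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.symmetry not in SYMMETRY_CLASSES:
            raise ValueError(
                f"unknown symmetry class {self.symmetry!r}; "
                f"expected one of {SYMMETRY_CLASSES}"
            )

    @property
    def n_strokes(self) -> int:
        return self.n_horizontal + self.n_vertical + self.n_oblique

    @property
    def n_cardinal(self) -> int:
        return self.n_horizontal + self.n_vertical


Segment = tuple[float, float, float, float]


@dataclass(frozen=True)
class GlyphGeometry:
    """A letter as a set of straight-line segments in glyph coordinates.

    x increases rightward and y increases upward, so a "vertical" stroke in
    the typographic sense has constant x. The segment list may be empty
    (curve-only letter); zero-length segments are rejected.
    """

    letter_id: str
    segments: tuple[Segment, ...] = ()

    def __post_init__(self) -> None:
        segs = tuple(tuple(float(v) for v in s) for s in self.segments)
        for s in segs:
            if len(s) != 4:
                raise ValueError(f"segment must be (x1, y1, x2, y2), got {s!r}")
            if s[0] == s[2] and s[1] == s[3]:
                raise ValueError(f"zero-length segment {s!r} in letter {self.letter_id!r}")
        object.__setattr__(self, "segments", segs)


@dataclass
class Script:
    """Metadata plus letters for one writing system."""

    script_code: str
    family: str
    status: str
    direction: str = "other"
    ancestors: list[str] = field(default_factory=list)
    letters: list[LetterCoding] = field(default_factory=list)
    glyphs: list[GlyphGeometry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in STATUS_VALUES:
            raise ValueError(
                f"script {self.script_code!r}: unknown status {self.status!r}; "
                f"expected one of {STATUS_VALUES}"
            )
        if self.direction not in DIRECTION_VALUES:
            raise ValueError(
                f"script {self.script_code!r}: unknown direction {self.direction!r}; "
                f"expected one of {DIRECTION_VALUES}"
            )
        if len(set(self.ancestors)) != len(self.ancestors):
            raise ValueError(
                f"script {self.script_code!r}: duplicate ancestor reference"
            )


@dataclass(frozen=True)
class BranchEvent:
    """One documented branching-out event: a descendant forming from an ancestor."""

    ancestor: str
    descendant: str

    def __post_init__(self) -> None:
        if self.ancestor == self.descendant:
            raise ValueError(f"branch event {self.ancestor!r} -> itself is not allowed")


@dataclass
class MeasureRecord:
    """The three legibility measures for one script, with audit counts.

    Each measure is either a defined float with the number of letters that
    produced it, or ``None`` with a reason code in the matching ``*_reason``
    field.
    """

    script_code: str
    cardinality: Optional[float] = None
    cardinality_n: int = 0
    cardinality_reason: str = ""
    separation_index: Optional[float] = None
    separation_n: int = 0
    separation_reason: str = ""
    vsym_dominance: Optional[float] = None
    vsym_n: int = 0
    vsym_reason: str = ""
    symmetric_proportion: Optional[float] = None
    n_letters: int = 0


class ScriptCollection:
    """An ordered mapping of script_code -> Script with uniqueness enforced."""

    def __init__(self, scripts: Iterable[Script] = ()):
        self._scripts: dict[str, Script] = {}
        for s in scripts:
            self.add(s)

    def add(self, script: Script) -> None:
        if script.script_code in self._scripts:
            raise ValueError(f"duplicate script_code {script.script_code!r}")
        self._scripts[script.script_code] = script

    def __getitem__(self, code: str) -> Script:
        return self._scripts[code]

    def __contains__(self, code: str) -> bool:
        return code in self._scripts

    def __iter__(self):
        return iter(self._scripts.values())

    def __len__(self) -> int:
        return len(self._scripts)

    @property
    def codes(self) -> list[str]:
        return list(self._scripts)

    def resolve_events(self, events: Sequence[BranchEvent]) -> None:
        """Raise if any event endpoint is missing from the collection."""
        for ev in events:
            for code in (ev.ancestor, ev.descendant):
                if code not in self._scripts:
                    raise KeyError(
                        f"branch event {ev.ancestor}->{ev.descendant}: "
                        f"script {code!r} not in collection"
                    )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScriptCollection):
            return NotImplemented
        return self._scripts == other._scripts
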