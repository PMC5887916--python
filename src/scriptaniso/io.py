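"""Readers and writers for the tabular formats.

Canonical format is UTF-8 TSV with a header row; lines starting with ``#``
are manifest/comment lines and are skipped on read. A :class:`TableDialect`
maps foreign column names and delimiters onto the canonical schema, which is
how externally deposited datasets are adapted without editing them.

Canonical schemas::

    scripts.tsv   script  family  status  direction  ancestors
    letters.tsv   script  letter  h  v  o  symmetry
    segments.tsv  script  letter  x1  y1  x2  y2
    measures.tsv  one row per script, measures + audit counts + reasons
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .model import (
    DIRECTION_VALUES,
    STATUS_VALUES,
    BranchEvent,
    GlyphGeometry,
    LetterCoding,
    MeasureRecord,
    Script,
    ScriptCollection,
)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


class IntegrityError(ValueError):
    """Cross-row or cross-file consistency violation (e.g. duplicate codes)."""


@dataclass
class TableDialect:
    """Column-name mapping for adapting foreign tables to the canonical schema.

    ``columns`` maps canonical names (script, family, status, ...) to the
    column names used in the file. Unmapped names are assumed canonical.
    ``status_map`` / ``direction_map`` translate foreign category tokens
    (e.g. "living" -> "live") before validation.
    """

    columns: dict[str, str] = field(default_factory=dict)
    sep: str = "\t"
    ancestors_delimiter: str = ";"
    status_map: dict[str, str] = field(default_factory=dict)
    direction_map: dict[str, str] = field(default_factory=dict)

    def col(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


CANONICAL = TableDialect()


def _read_table(path: PathLike, dialect: TableDialect) -> pd.DataFrame:
    df = pd.read_csv(path, sep=dialect.sep, comment="#", dtype=str, keep_default_na=False)
    return df


def _require_columns(df: pd.DataFrame, names: Iterable[str], path: PathLike) -> None:
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")


def read_scripts_table(
    path: PathLike, dialect: TableDialect = CANONICAL
) -> ScriptCollection:
    """Read a scripts table into a ScriptCollection (letters left empty)."""
    df = _read_table(path, dialect)
    cols = {k: dialect.col(k) for k in ("script", "family", "status", "direction", "ancestors")}
    _require_columns(df, [cols["script"], cols["family"], cols["status"]], path)
    collection = ScriptCollection()
    for idx, row in df.iterrows():
        code = row[cols["script"]].strip()
        status = row[cols["status"]].strip()
        status = dialect.status_map.get(status, status)
        if status not in STATUS_VALUES:
            raise FormatError(f"{path}: row {idx + 2}: unknown status token {status!r}")
        direction = row.get(cols["direction"], "other")
        direction = (direction or "other").strip()
        direction = dialect.direction_map.get(direction, direction)
        if direction not in DIRECTION_VALUES:
            raise FormatError(f"{path}: row {idx + 2}: unknown direction token {direction!r}")
        raw_anc = row.get(cols["ancestors"], "") or ""
        ancestors = [a.strip() for a in raw_anc.split(dialect.ancestors_delimiter) if a.strip()]
        script = Script(
            script_code=code,
            family=row[cols["family"]].strip(),
            status=status,
            direction=direction,
            ancestors=ancestors,
        )
        try:
            collection.add(script)
        except ValueError as e:
            raise IntegrityError(f"{path}: row {idx + 2}: {e}") from e
    return collection


def write_scripts_table(
    collection: ScriptCollection,
    path: PathLike,
    dialect: TableDialect = CANONICAL,
    header_lines: Sequence[str] = (),
) -> None:
    rows = []
    for s in collection:
        rows.append(
            {
                "script": s.script_code,
                "family": s.family,
                "status": s.status,
                "direction": s.direction,
                "ancestors": dialect.ancestors_delimiter.join(s.ancestors),
            }
        )
    _write_tsv(pd.DataFrame(rows, columns=["script", "family", "status", "direction", "ancestors"]), path, header_lines)


def read_letter_codings(path: PathLike, dialect: TableDialect = CANONICAL) -> dict[str, list[LetterCoding]]:
    """Read per-letter stroke codings, grouped by script code."""
    df = _read_table(path, dialect)
    cols = [dialect.col(k) for k in ("script", "letter", "h", "v", "o", "symmetry")]
    _require_columns(df, cols, path)
    out: dict[str, list[LetterCoding]] = {}
    c_script, c_letter, c_h, c_v, c_o, c_sym = cols
    for idx, row in df.iterrows():
        counts = {}
        for name, col in (("n_horizontal", c_h), ("n_vertical", c_v), ("n_oblique", c_o)):
            raw = row[col].strip()
            try:
                value = int(raw)
            except ValueError:
                raise FormatError(f"{path}: row {idx + 2}: non-integer count {raw!r}") from None
            counts[name] = value
        try:
            coding = LetterCoding(letter_id=row[c_letter], symmetry=row[c_sym].strip(), **counts)
        except ValueError as e:
            raise FormatError(f"{path}: row {idx + 2}: {e}") from e
        out.setdefault(row[c_script].strip(), []).append(coding)
    return out


def write_letter_codings(
    codings: Mapping[str, Sequence[LetterCoding]],
    path: PathLike,
    header_lines: Sequence[str] = (),
) -> None:
    rows = [
        {
            "script": code,
            "letter": l.letter_id,
            "h": l.n_horizontal,
            "v": l.n_vertical,
            "o": l.n_oblique,
            "symmetry": l.symmetry,
        }
        for code, letters in codings.items()
        for l in letters
    ]
    _write_tsv(pd.DataFrame(rows, columns=["script", "letter", "h", "v", "o", "symmetry"]), path, header_lines)


def read_glyph_segments(path: PathLike, dialect: TableDialect = CANONICAL) -> dict[str, list[GlyphGeometry]]:
    """Read straight-line segments grouped into glyphs by (script, letter)."""
    df = _read_table(path, dialect)
    cols = [dialect.col(k) for k in ("script", "letter", "x1", "y1", "x2", "y2")]
    _require_columns(df, cols, path)
    c_script, c_letter, *coords = cols
    grouped: dict[tuple[str, str], list] = {}
    order: list[tuple[str, str]] = []
    for idx, row in df.iterrows():
        try:
            seg = tuple(float(row[c]) for c in coords)
        except ValueError:
            raise FormatError(f"{path}: row {idx + 2}: non-numeric coordinate") from None
        if seg[0] == seg[2] and seg[1] == seg[3]:
            raise FormatError(f"{path}: row {idx + 2}: zero-length segment {seg}")
        key = (row[c_script].strip(), row[c_letter])
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(seg)
    out: dict[str, list[GlyphGeometry]] = {}
    for (script, letter) in order:
        out.setdefault(script, []).append(
            GlyphGeometry(letter_id=letter, segments=tuple(grouped[(script, letter)]))
        )
    return out


def write_glyph_segments(
    glyphs: Mapping[str, Sequence[GlyphGeometry]],
    path: PathLike,
    header_lines: Sequence[str] = (),
) -> None:
    rows = [
        {"script": code, "letter": g.letter_id, "x1": s[0], "y1": s[1], "x2": s[2], "y2": s[3]}
        for code, gs in glyphs.items()
        for g in gs
        for s in g.segments
    ]
    _write_tsv(pd.DataFrame(rows, columns=["script", "letter", "x1", "y1", "x2", "y2"]), path, header_lines)


def read_branch_events(path: PathLike, dialect: TableDialect = CANONICAL) -> list[BranchEvent]:
    df = _read_table(path, dialect)
    cols = [dialect.col(k) for k in ("ancestor", "descendant")]
    _require_columns(df, cols, path)
    return [BranchEvent(ancestor=row[cols[0]].strip(), descendant=row[cols[1]].strip()) for _, row in df.iterrows()]


def write_branch_events(events: Sequence[BranchEvent], path: PathLike, header_lines: Sequence[str] = ()) -> None:
    rows = [{"ancestor": e.ancestor, "descendant": e.descendant} for e in events]
    _write_tsv(pd.DataFrame(rows, columns=["ancestor", "descendant"]), path, header_lines)


MEASURE_COLUMNS = [
    "script",
    "cardinality",
    "cardinality_n",
    "cardinality_reason",
    "separation",
    "separation_n",
    "separation_reason",
    "vsym",
    "vsym_n",
    "vsym_reason",
    "symmetric_prop",
    "n_letters",
]


def measures_frame(records: Sequence[MeasureRecord]) -> pd.DataFrame:
    """MeasureRecords as a DataFrame in the measures.tsv column order."""
    rows = []
    for r in records:
        rows.append(
            {
                "script": r.script_code,
                "cardinality": r.cardinality,
                "cardinality_n": r.cardinality_n,
                "cardinality_reason": r.cardinality_reason,
                "separation": r.separation_index,
                "separation_n": r.separation_n,
                "separation_reason": r.separation_reason,
                "vsym": r.vsym_dominance,
                "vsym_n": r.vsym_n,
                "vsym_reason": r.vsym_reason,
                "symmetric_prop": r.symmetric_proportion,
                "n_letters": r.n_letters,
            }
        )
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)


def write_measures(records: Sequence[MeasureRecord], path: PathLike, header_lines: Sequence[str] = ()) -> None:
    _write_tsv(measures_frame(records), path, header_lines, float_format="%.10g")


def read_measures(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["script"], path)
    return df


def _write_tsv(
    df: pd.DataFrame,
    path: PathLike,
    header_lines: Sequence[str] = (),
    float_format: Optional[str] = None,
) -> None:
    """Write a TSV atomically, with optional '#'-prefixed manifest header."""
    path = Path(path)
    buf = _io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False, float_format=float_format)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(buf.getvalue(), encoding="utf-8")
    tmp.replace(path)
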