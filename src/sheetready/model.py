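"""Neutral in-memory model of spreadsheet content.

The model is deliberately independent of any file format: readers populate
it from .xlsx or CSV files (see :mod:`sheetready.io`), the rule checker and
all downstream operations consume it, and writers serialise it back.

Conventions
-----------
* Cell addressing is 1-based ``(row, column)`` internally and A1 notation
  for display.
* Colors are normalised ``#RRGGBB`` hex; absence of an explicit fill or
  font color is represented by ``None`` ("default"), never a hex value.
* Formula cells carry both the formula text and the cached computed value
  when one is present; checks operate on cached values.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Optional, Union

__all__ = [
    "ValueKind",
    "CellAddress",
    "Rect",
    "Cell",
    "EmbeddedObject",
    "Sheet",
    "Workbook",
    "value_kind_of",
    "column_letter",
    "column_index",
]

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def column_letter(index: int) -> str:
    """1-based column index -> spreadsheet column letters (1 -> 'A')."""
    if index < 1:
        raise ValueError(f"column index must be >= 1, got {index}")
    out = ""
    n = index
    while n > 0:
        n, rem = divmod(n - 1, 26)
        out = _LETTERS[rem] + out
    return out


def column_index(letters: str) -> int:
    """Spreadsheet column letters -> 1-based index ('A' -> 1)."""
    if not letters or not all(c in _LETTERS for c in letters.upper()):
        raise ValueError(f"invalid column letters: {letters!r}")
    n = 0
    for c in letters.upper():
        n = n * 26 + (_LETTERS.index(c) + 1)
    return n


_A1_RE = re.compile(r"^([A-Za-z]{1,3})([0-9]+)$")


class ValueKind(str, Enum):
    EMPTY = "empty"
    NUMBER = "number"
    TEXT = "text"
    DATE = "date"
    BOOLEAN = "boolean"
    ERROR = "error"


@dataclass(frozen=True, order=True)
class CellAddress:
    """Location of a single cell: sheet name plus 1-based row/column."""

    sheet_name: str
    row: int
    column: int

    def __post_init__(self):
        if self.row < 1 or self.column < 1:
            raise ValueError(f"cell address out of range: {self}")

    @property
    def a1(self) -> str:
        return f"{column_letter(self.column)}{self.row}"

    @classmethod
    def from_a1(cls, sheet_name: str, a1: str) -> "CellAddress":
        m = _A1_RE.match(a1)
        if not m:
            raise ValueError(f"invalid A1 reference: {a1!r}")
        return cls(sheet_name, int(m.group(2)), column_index(m.group(1)))

    def __str__(self) -> str:
        return f"{self.sheet_name}!{self.a1}"


@dataclass(frozen=True, order=True)
class Rect:
    """Inclusive 1-based rectangle (top, left, bottom, right)."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self):
        if not (1 <= self.top <= self.bottom and 1 <= self.left <= self.right):
            raise ValueError(f"degenerate rectangle: {self}")

    @property
    def a1(self) -> str:
        return (
            f"{column_letter(self.left)}{self.top}:"
            f"{column_letter(self.right)}{self.bottom}"
        )

    @classmethod
    def from_a1(cls, ref: str) -> "Rect":
        parts = ref.split(":")
        if len(parts) == 1:
            parts = [parts[0], parts[0]]
        (c1, r1), (c2, r2) = (_split_a1(p) for p in parts)
        return cls(min(r1, r2), min(c1, c2), max(r1, r2), max(c1, c2))

    def contains(self, row: int, column: int) -> bool:
        return self.top <= row <= self.bottom and self.left <= column <= self.right

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.right < other.left
            or other.right < self.left
            or self.bottom < other.top
            or other.bottom < self.top
        )

    def cells(self) -> Iterator[tuple[int, int]]:
        for r in range(self.top, self.bottom + 1):
            for c in range(self.left, self.right + 1):
                yield r, c

    @property
    def n_rows(self) -> int:
        return self.bottom - self.top + 1

    @property
    def n_cols(self) -> int:
        return self.right - self.left + 1


def _split_a1(ref: str) -> tuple[int, int]:
    m = _A1_RE.match(ref)
    if not m:
        raise ValueError(f"invalid A1 reference: {ref!r}")
    return column_index(m.group(1)), int(m.group(2))


Location = Union[CellAddress, Rect]

Scalar = Union[None, int, float, str, bool, _dt.date, _dt.datetime]

_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_DATE_RE = re.compile(
    r"^\d{4}-\d{2}-\d{2}([T ]\d{2}:\d{2}(:\d{2}(\.\d+)?)?)?$"
)


def value_kind_of(raw: Scalar) -> ValueKind:
    """Classify a raw cell value into a :class:`ValueKind`.

    Total and deterministic.  Text values are sniffed the way CSV input is
    typed: a string is a *number* iff it parses as a decimal or
    scientific-notation literal, a *date* iff it parses as ISO 8601, and
    plain *text* otherwise.  Native numbers, booleans and date objects map
    directly.
    """
    if raw is None:
        return ValueKind.EMPTY
    if isinstance(raw, bool):
        return ValueKind.BOOLEAN
    if isinstance(raw, (int, float)):
        return ValueKind.NUMBER
    if isinstance(raw, (_dt.date, _dt.datetime)):
        return ValueKind.DATE
    if isinstance(raw, str):
        if raw == "":
            return ValueKind.EMPTY
        if _NUMBER_RE.match(raw):
            return ValueKind.NUMBER
        if _DATE_RE.match(raw):
            try:
                _parse_iso(raw)
                return ValueKind.DATE
            except ValueError:
                return ValueKind.TEXT
        return ValueKind.TEXT
    return ValueKind.TEXT


def sniff_csv_value(raw: str) -> Scalar:
    """Convert a CSV field to its typed value per the sniffing rules."""
    kind = value_kind_of(raw)
    if kind is ValueKind.EMPTY:
        return None
    if kind is ValueKind.NUMBER:
        f = float(raw)
        if f.is_integer() and "." not in raw and "e" not in raw.lower():
            return int(raw)
        return f
    if kind is ValueKind.DATE:
        return _parse_iso(raw)
    return raw


def _parse_iso(text: str) -> Union[_dt.date, _dt.datetime]:
    if len(text) == 10:
        return _dt.date.fromisoformat(text)
    return _dt.datetime.fromisoformat(text.replace(" ", "T"))


@dataclass
class Cell:
    """One cell: value, classification, and export-hostile decorations."""

    address: CellAddress
    raw_value: Scalar = None
    value_kind: ValueKind = ValueKind.EMPTY
    formula_text: Optional[str] = None
    comment_text: Optional[str] = None
    fill_color: Optional[str] = None
    font_color: Optional[str] = None

    def __post_init__(self):
        if self.raw_value is None and self.value_kind not in (
            ValueKind.EMPTY,
            ValueKind.ERROR,
        ):
            raise ValueError(
                f"cell {self.address} has no value but kind {self.value_kind}"
            )

    @property
    def is_empty(self) -> bool:
        return self.value_kind is ValueKind.EMPTY

    @property
    def has_formula(self) -> bool:
        return self.formula_text is not None


class ObjectKind(str, Enum):
    CHART = "chart"
    PICTURE = "picture"
    PIVOT_TABLE = "pivot_table"


@dataclass(frozen=True)
class EmbeddedObject:
    """Presence-and-anchor record of a chart/picture/pivot table."""

    kind: ObjectKind
    anchor: CellAddress


@dataclass
class Sheet:
    """A sparse grid of cells plus sheet-level decorations."""

    name: str
    cells: dict[tuple[int, int], Cell] = field(default_factory=dict)
    merged_ranges: list[Rect] = field(default_factory=list)
    embedded_objects: list[EmbeddedObject] = field(default_factory=list)

    def cell_at(self, row: int, column: int) -> Optional[Cell]:
        return self.cells.get((row, column))

    def value_at(self, row: int, column: int) -> Scalar:
        cell = self.cells.get((row, column))
        return None if cell is None else cell.raw_value

    def kind_at(self, row: int, column: int) -> ValueKind:
        cell = self.cells.get((row, column))
        return ValueKind.EMPTY if cell is None else cell.value_kind

    def is_blank(self, row: int, column: int) -> bool:
        return self.kind_at(row, column) is ValueKind.EMPTY

    def set_value(
        self,
        row: int,
        column: int,
        value: Scalar,
        *,
        kind: Optional[ValueKind] = None,
        **attrs,
    ) -> Cell:
        """Create or update a cell; kind is inferred unless given."""
        addr = CellAddress(self.name, row, column)
        cell = self.cells.get((row, column))
        if cell is None:
            cell = Cell(address=addr)
            self.cells[(row, column)] = cell
        cell.raw_value = value
        cell.value_kind = value_kind_of(value) if kind is None else kind
        for name, val in attrs.items():
            setattr(cell, name, val)
        return cell

    def clear_value(self, row: int, column: int) -> None:
        cell = self.cells.get((row, column))
        if cell is not None:
            cell.raw_value = None
            cell.value_kind = ValueKind.EMPTY
            if (
                cell.formula_text is None
                and cell.comment_text is None
                and cell.fill_color is None
                and cell.font_color is None
            ):
                del self.cells[(row, column)]

    @property
    def used_range(self) -> Optional[Rect]:
        """Minimal rectangle covering all non-empty cells, None if blank."""
        coords = [
            (r, c) for (r, c), cell in self.cells.items() if not cell.is_empty
        ]
        if not coords:
            return None
        rows = [r for r, _ in coords]
        cols = [c for _, c in coords]
        return Rect(min(rows), min(cols), max(rows), max(cols))

    @property
    def is_empty(self) -> bool:
        return self.used_range is None

    def validate(self) -> None:
        for i, a in enumerate(self.merged_ranges):
            for b in self.merged_ranges[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(
                        f"overlapping merged ranges on {self.name!r}: "
                        f"{a.a1} and {b.a1}"
                    )
        for obj in self.embedded_objects:
            if obj.anchor.sheet_name != self.name:
                raise ValueError(
                    f"embedded object anchored on {obj.anchor.sheet_name!r} "
                    f"attached to sheet {self.name!r}"
                )


class SourceFormat(str, Enum):
    XLSX = "xlsx"
    CSV = "csv"


@dataclass
class Workbook:
    """An ordered collection of sheets plus document properties."""

    sheets: list[Sheet] = field(default_factory=list)
    doc_properties: dict[str, str] = field(default_factory=dict)
    source_path: str = ""
    source_format: SourceFormat = SourceFormat.XLSX

    def sheet(self, name: str) -> Sheet:
        for s in self.sheets:
            if s.name == name:
                return s
        raise KeyError(f"no sheet named {name!r}")

    @property
    def sheet_names(self) -> list[str]:
        return [s.name for s in self.sheets]

    def validate(self) -> None:
        names = self.sheet_names
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate sheet names: {names}")
        if self.source_format is SourceFormat.CSV and len(self.sheets) != 1:
            raise ValueError("CSV-sourced workbooks must have exactly one sheet")
        for s in self.sheets:
            s.validate()

    def copy(self) -> "Workbook":
        """Deep-enough copy for pure remediation transforms."""
        new_sheets = []
        for s in self.sheets:
            new_cells = {
                key: replace(cell) for key, cell in s.cells.items()
            }
            new_sheets.append(
                Sheet(
                    name=s.name,
                    cells=new_cells,
                    merged_ranges=list(s.merged_ranges),
                    embedded_objects=list(s.embedded_objects),
                )
            )
        return Workbook(
            sheets=new_sheets,
            doc_properties=dict(self.doc_properties),
            source_path=self.source_path,
            source_format=self.source_format,
        )
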