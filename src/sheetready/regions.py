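"""Table-region detection and header-row inference.

Contiguous data blocks are found by recursively splitting the used range
at rows and columns that are entirely empty across the current block —
empty rows/columns act as table separators.  The resulting regions are
pairwise disjoint rectangles that together cover every non-empty cell,
returned in top-left reading order.

These heuristics are reconstructions: the original tool's region and
header logic was never published, so the predicates here are documented
choices, not transcriptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import Rect, Sheet, ValueKind

__all__ = ["TableRegion", "detect_regions", "detect_header"]


@dataclass(frozen=True)
class TableRegion:
    """A maximal contiguous data block on one sheet."""

    sheet_name: str
    bounds: Rect
    header_row: Optional[int] = None
    header_row_count: int = 0

    @property
    def data_top(self) -> int:
        """First row of the data body (below any header rows)."""
        return self.bounds.top + self.header_row_count


def detect_regions(sheet: Sheet) -> list[TableRegion]:
    """Split the used range into maximal contiguous regions.

    Returns regions with headers already inferred, in reading order.
    Invariant to trailing empty rows/columns: only the used range is
    examined.  An empty sheet yields ``[]``.
    """
    used = sheet.used_range
    if used is None:
        return []
    rects: list[Rect] = []
    _split(sheet, used, rects)
    rects.sort(key=lambda r: (r.top, r.left))
    regions = []
    for rect in rects:
        stub = TableRegion(sheet_name=sheet.name, bounds=rect)
        header_row, count = detect_header(stub, sheet)
        regions.append(
            TableRegion(
                sheet_name=sheet.name,
                bounds=rect,
                header_row=header_row,
                header_row_count=count,
            )
        )
    return regions


def _split(sheet: Sheet, block: Rect, out: list[Rect]) -> None:
    block = _trim(sheet, block)
    if block is None:
        return
    empty_rows = [
        r
        for r in range(block.top, block.bottom + 1)
        if _row_empty(sheet, r, block)
    ]
    if empty_rows:
        for band in _bands(block.top, block.bottom, empty_rows):
            _split(sheet, Rect(band[0], block.left, band[1], block.right), out)
        return
    empty_cols = [
        c
        for c in range(block.left, block.right + 1)
        if _col_empty(sheet, c, block)
    ]
    if empty_cols:
        for band in _bands(block.left, block.right, empty_cols):
            _split(sheet, Rect(block.top, band[0], block.bottom, band[1]), out)
        return
    out.append(block)


def _trim(sheet: Sheet, block: Rect) -> Optional[Rect]:
    coords = [
        (r, c)
        for (r, c), cell in sheet.cells.items()
        if not cell.is_empty and block.contains(r, c)
    ]
    if not coords:
        return None
    rows = [r for r, _ in coords]
    cols = [c for _, c in coords]
    return Rect(min(rows), min(cols), max(rows), max(cols))


def _row_empty(sheet: Sheet, row: int, block: Rect) -> bool:
    return all(
        sheet.is_blank(row, c) for c in range(block.left, block.right + 1)
    )


def _col_empty(sheet: Sheet, col: int, block: Rect) -> bool:
    return all(
        sheet.is_blank(r, col) for r in range(block.top, block.bottom + 1)
    )


def _bands(start: int, stop: int, gaps: list[int]) -> list[tuple[int, int]]:
    """Maximal runs of indices in [start, stop] not in ``gaps``."""
    gapset = set(gaps)
    bands = []
    lo = None
    for i in range(start, stop + 2):
        if i <= stop and i not in gapset:
            if lo is None:
                lo = i
        elif lo is not None:
            bands.append((lo, i - 1))
            lo = None
    return bands


def detect_header(
    region: TableRegion, sheet: Sheet
) -> tuple[Optional[int], int]:
    """Infer (header_row, header_row_count) for a region.

    The first row qualifies as a header iff every cell across the region
    width is present, text-typed, and unique within the row.  Further
    consecutive all-text full rows extend the header block only while at
    least half the region's columns hold a non-text value somewhere below
    the candidate row — so an all-text data table keeps a single-row
    header instead of being swallowed whole.
    """
    bounds = region.bounds
    cols = range(bounds.left, bounds.right + 1)

    first = [sheet.cell_at(bounds.top, c) for c in cols]
    if any(c is None or c.value_kind is not ValueKind.TEXT for c in first):
        return None, 0
    labels = [c.raw_value for c in first]
    if len(set(labels)) != len(labels):
        return None, 0

    count = 1
    row = bounds.top + 1
    while row <= bounds.bottom:
        candidates = [sheet.cell_at(row, c) for c in cols]
        if any(
            c is None or c.value_kind is not ValueKind.TEXT
            for c in candidates
        ):
            break
        non_text_below = sum(
            1
            for c in cols
            if any(
                sheet.kind_at(r, c)
                not in (ValueKind.TEXT, ValueKind.EMPTY)
                for r in range(row + 1, bounds.bottom + 1)
            )
        )
        if non_text_below * 2 < bounds.n_cols:
            break
        count += 1
        row += 1
    return bounds.top, count
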