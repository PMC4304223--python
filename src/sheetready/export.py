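"""CSV export with multi-sheet splitting, and bulk remediation transforms.

Every remediation returns a new workbook; inputs are never mutated.
Applying all auto-fixes then re-running the checker leaves the rules
embedded_objects / embedded_comments / color_coding / merged_cells clean.
"""

from __future__ import annotations

import csv
import datetime as _dt
import re
from pathlib import Path
from typing import Union

from .errors import ExportError
from .model import Scalar, Sheet, ValueKind, Workbook
from .regions import detect_regions

__all__ = [
    "export_csv",
    "comments_to_column",
    "strip_formatting",
    "strip_objects",
    "unmerge_fill",
    "apply_all_fixes",
]


def serialize_value(value: Scalar, kind: ValueKind) -> str:
    """Serialise one cell value for CSV output.

    Numbers use the shortest round-trip decimal form, dates ISO 8601;
    quoting is the csv module's RFC 4180 minimal quoting.
    """
    if value is None or kind is ValueKind.ERROR:
        return ""
    if kind is ValueKind.BOOLEAN:
        return "TRUE" if value else "FALSE"
    if kind is ValueKind.NUMBER:
        if isinstance(value, float) and value.is_integer():
            return repr(value)
        return repr(value) if isinstance(value, float) else str(value)
    if kind is ValueKind.DATE:
        if isinstance(value, _dt.datetime):
            return value.isoformat(sep="T")
        return value.isoformat()
    return str(value)


def _sanitize_name(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_-]", "_", name)


def export_csv(
    wb: Workbook,
    out_dir: Union[str, Path],
    *,
    line_ending: str = "lf",
) -> list[Path]:
    """Write one RFC 4180 CSV per non-empty sheet; returns paths written.

    A single non-empty sheet exports as ``<stem>.csv``; multiple sheets
    as ``<stem>_<sheetname>.csv``.  Comments, colors, merges and embedded
    objects are dropped (merged ranges keep the anchor value top-left).
    """
    if line_ending not in ("lf", "crlf"):
        raise ExportError(f"unknown line ending {line_ending!r}")
    terminator = "\n" if line_ending == "lf" else "\r\n"
    non_empty = [s for s in wb.sheets if not s.is_empty]
    if not non_empty:
        raise ExportError("nothing to export: workbook has no non-empty sheet")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = Path(wb.source_path).stem if wb.source_path else "workbook"

    names: list[str] = []
    seen: set[str] = set()
    for sheet in non_empty:
        if len(non_empty) == 1:
            base = _sanitize_name(stem)
        else:
            base = f"{_sanitize_name(stem)}_{_sanitize_name(sheet.name)}"
        name, n = base, 1
        while name in seen:
            n += 1
            name = f"{base}_{n}"
        seen.add(name)
        names.append(name)

    paths = []
    for sheet, name in zip(non_empty, names):
        path = out_dir / f"{name}.csv"
        _write_sheet_csv(sheet, path, terminator)
        paths.append(path)
    return paths


def _write_sheet_csv(sheet: Sheet, path: Path, terminator: str) -> None:
    used = sheet.used_range
    assert used is not None
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator=terminator)
        for row in range(1, used.bottom + 1):
            record = []
            for col in range(1, used.right + 1):
                cell = sheet.cell_at(row, col)
                if cell is None:
                    record.append("")
                else:
                    record.append(
                        serialize_value(cell.raw_value, cell.value_kind)
                    )
            writer.writerow(record)


# ---------------------------------------------------------------------------
# remediation transforms (all pure, all idempotent)


def comments_to_column(wb: Workbook) -> Workbook:
    """Move cell comments into a new rightmost "Comments" column per region.

    For each region containing commented cells, a column is appended to
    its right; each row holds that row's comment texts joined with "; "
    in column order.  All comments everywhere are then removed.
    """
    out = wb.copy()
    for sheet in out.sheets:
        for region in detect_regions(sheet):
            bounds = region.bounds
            row_comments: dict[int, list[str]] = {}
            for row in range(bounds.top, bounds.bottom + 1):
                texts = []
                for col in range(bounds.left, bounds.right + 1):
                    cell = sheet.cell_at(row, col)
                    if cell is not None and cell.comment_text is not None:
                        texts.append(cell.comment_text)
                if texts:
                    row_comments[row] = texts
            if not row_comments:
                continue
            new_col = bounds.right + 1
            sheet.set_value(bounds.top, new_col, "Comments")
            for row, texts in row_comments.items():
                if row == bounds.top:
                    joined = "; ".join(["Comments"] + texts)
                    sheet.set_value(row, new_col, joined)
                else:
                    sheet.set_value(row, new_col, "; ".join(texts))
        for cell in sheet.cells.values():
            cell.comment_text = None
    return out


def strip_formatting(wb: Workbook) -> Workbook:
    """Remove all fill and font colors."""
    out = wb.copy()
    for sheet in out.sheets:
        for key in list(sheet.cells):
            cell = sheet.cells[key]
            cell.fill_color = None
            cell.font_color = None
            if cell.is_empty and cell.comment_text is None and (
                cell.formula_text is None
            ):
                del sheet.cells[key]
    return out


def strip_objects(wb: Workbook) -> Workbook:
    """Remove all embedded charts, pictures and pivot tables."""
    out = wb.copy()
    for sheet in out.sheets:
        sheet.embedded_objects = []
    return out


def unmerge_fill(wb: Workbook) -> Workbook:
    """Un-merge every range, replicating the anchor value into each cell."""
    out = wb.copy()
    for sheet in out.sheets:
        for rect in sheet.merged_ranges:
            anchor = sheet.cell_at(rect.top, rect.left)
            if anchor is None or anchor.is_empty:
                continue
            for row, col in rect.cells():
                sheet.set_value(
                    row, col, anchor.raw_value, kind=anchor.value_kind
                )
        sheet.merged_ranges = []
    return out


def apply_all_fixes(wb: Workbook) -> Workbook:
    """All automatic remedies: objects, comments, formatting, merges."""
    return strip_formatting(
        comments_to_column(unmerge_fill(strip_objects(wb)))
    )
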