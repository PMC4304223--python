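"""Readers and writers: .xlsx (Office Open XML) and RFC 4180 CSV.

``read_workbook(write_workbook(wb))`` round-trips values, kinds, comments,
merged ranges, fill/font colors and sheet order.  Embedded charts and
pictures round-trip as presence + anchor; pivot tables are modelled
in-memory only (openpyxl cannot author them), which the writer reports.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io as _io
from pathlib import Path
from typing import Union

import openpyxl
from openpyxl.comments import Comment
from openpyxl.styles import Font, PatternFill
from openpyxl.styles.colors import COLOR_INDEX
from openpyxl.utils import get_column_letter

from .errors import FormatError
from .model import (
    Cell,
    CellAddress,
    EmbeddedObject,
    ObjectKind,
    Rect,
    Sheet,
    SourceFormat,
    ValueKind,
    Workbook,
    sniff_csv_value,
)

__all__ = ["read_workbook", "write_workbook"]

#: Excel worksheet error literals (data_type 'e').
_ERROR_LITERALS = {
    "#DIV/0!", "#N/A", "#NAME?", "#NULL!", "#NUM!", "#REF!", "#VALUE!",
}


def read_workbook(path: Union[str, Path]) -> Workbook:
    """Read an .xlsx or .csv file into the neutral workbook model."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".xlsx":
        return _read_xlsx(path)
    if suffix == ".csv":
        return _read_csv(path)
    raise FormatError(
        f"unsupported file extension {suffix!r} for {path}; "
        "expected .xlsx or .csv"
    )


def write_workbook(wb: Workbook, path: Union[str, Path]) -> Path:
    """Write the model to ``path`` (.xlsx); returns the path written."""
    wb.validate()
    path = Path(path)
    try:
        book = _to_openpyxl(wb)
        book.save(path)
    except OSError as exc:
        raise FormatError(f"cannot write workbook to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# xlsx reading

def _read_xlsx(path: Path) -> Workbook:
    try:
        book = openpyxl.load_workbook(path, data_only=False)
        cached = openpyxl.load_workbook(path, data_only=True)
    except Exception as exc:  # openpyxl raises a zoo of exception types
        raise FormatError(f"cannot read workbook {path}: {exc}") from exc

    sheets = []
    for ws, ws_cached in zip(book.worksheets, cached.worksheets):
        sheets.append(_read_worksheet(ws, ws_cached))

    props = {}
    if book.properties.creator and book.properties.creator != "openpyxl":
        props["author"] = book.properties.creator
    if book.properties.title:
        props["title"] = book.properties.title
    if book.properties.created:
        props["created"] = book.properties.created.isoformat()

    model = Workbook(
        sheets=sheets,
        doc_properties=props,
        source_path=str(path),
        source_format=SourceFormat.XLSX,
    )
    model.validate()
    return model


def _read_worksheet(ws, ws_cached) -> Sheet:
    sheet = Sheet(name=ws.title)
    merged = [Rect(r.min_row, r.min_col, r.max_row, r.max_col)
              for r in ws.merged_cells.ranges]
    merged_cells = {
        (r, c) for rect in merged for (r, c) in rect.cells()
    }
    anchor_cells = {(rect.top, rect.left) for rect in merged}

    for row in ws.iter_rows():
        for cell in row:
            # non-anchor merged cells are openpyxl MergedCell placeholders
            if (cell.row, cell.column) in merged_cells and (
                cell.row, cell.column
            ) not in anchor_cells:
                continue
            model_cell = _read_cell(ws, ws_cached, cell, sheet.name)
            if model_cell is not None:
                sheet.cells[(cell.row, cell.column)] = model_cell

    sheet.merged_ranges = merged
    sheet.embedded_objects = _read_objects(ws)
    return sheet


def _read_cell(ws, ws_cached, cell, sheet_name):
    formula = None
    raw = cell.value
    kind = None
    if cell.data_type == "f":
        formula = raw if isinstance(raw, str) else None
        raw = ws_cached.cell(row=cell.row, column=cell.column).value

    if isinstance(raw, str) and (
        cell.data_type == "e" or raw in _ERROR_LITERALS
    ):
        kind, raw = ValueKind.ERROR, None
    elif raw is None:
        kind = ValueKind.EMPTY
    elif isinstance(raw, bool):
        kind = ValueKind.BOOLEAN
    elif isinstance(raw, (int, float)):
        kind = ValueKind.NUMBER
    elif isinstance(raw, _dt.datetime):
        # date-valued cells come back as midnight datetimes; normalise
        if raw.time() == _dt.time(0, 0):
            raw = raw.date()
        kind = ValueKind.DATE
    elif isinstance(raw, (_dt.date, _dt.time)):
        kind = ValueKind.DATE
    else:
        raw = str(raw)
        kind = ValueKind.TEXT if raw else ValueKind.EMPTY

    comment = cell.comment.text if cell.comment is not None else None
    fill = _read_fill(cell)
    font = _read_font_color(cell)

    if (
        kind is ValueKind.EMPTY
        and formula is None
        and comment is None
        and fill is None
        and font is None
    ):
        return None
    return Cell(
        address=CellAddress(sheet_name, cell.row, cell.column),
        raw_value=raw,
        value_kind=kind,
        formula_text=formula,
        comment_text=comment,
        fill_color=fill,
        font_color=font,
    )


def _normalize_color(color) -> str | None:
    """openpyxl Color -> '#RRGGBB', or None for default/theme colors."""
    if color is None:
        return None
    if color.type == "rgb" and isinstance(color.rgb, str):
        rgb = color.rgb
        if len(rgb) == 8:  # ARGB
            rgb = rgb[2:]
        return "#" + rgb.upper()
    if color.type == "indexed":
        try:
            argb = COLOR_INDEX[color.indexed]
        except (IndexError, TypeError):
            return None
        return "#" + argb[-6:].upper()
    # theme colors are left unresolved and treated as default
    return None


def _read_fill(cell) -> str | None:
    fill = cell.fill
    if fill is None or fill.patternType != "solid":
        return None
    return _normalize_color(fill.fgColor)


def _read_font_color(cell) -> str | None:
    font = cell.font
    if font is None:
        return None
    return _normalize_color(font.color)


def _read_objects(ws) -> list[EmbeddedObject]:
    objects = []
    for kind, attr in (
        (ObjectKind.CHART, "_charts"),
        (ObjectKind.PICTURE, "_images"),
    ):
        for obj in getattr(ws, attr, []):
            anchor = getattr(obj, "anchor", None)
            marker = getattr(anchor, "_from", None)
            if marker is None:
                row, col = 1, 1
            else:
                row, col = marker.row + 1, marker.col + 1
            objects.append(
                EmbeddedObject(kind, CellAddress(ws.title, row, col))
            )
    for pivot in getattr(ws, "_pivots", []):
        ref = getattr(getattr(pivot, "location", None), "ref", None)
        if ref:
            rect = Rect.from_a1(ref.split("!")[-1].replace("$", ""))
            anchor = CellAddress(ws.title, rect.top, rect.left)
        else:
            anchor = CellAddress(ws.title, 1, 1)
        objects.append(EmbeddedObject(ObjectKind.PIVOT_TABLE, anchor))
    return objects


# ---------------------------------------------------------------------------
# xlsx writing

def _to_openpyxl(wb: Workbook):
    book = openpyxl.Workbook()
    book.remove(book.active)
    for sheet in wb.sheets:
        ws = book.create_sheet(sheet.name)
        merged_non_anchor = {
            (r, c)
            for rect in sheet.merged_ranges
            for (r, c) in rect.cells()
            if (r, c) != (rect.top, rect.left)
        }
        for (row, col), cell in sorted(sheet.cells.items()):
            if (row, col) in merged_non_anchor:
                continue
            target = ws.cell(row=row, column=col)
            if cell.formula_text is not None:
                target.value = cell.formula_text
            elif cell.value_kind is ValueKind.ERROR:
                target.value = "#VALUE!"
            elif cell.raw_value is not None:
                target.value = cell.raw_value
            if cell.comment_text is not None:
                target.comment = Comment(cell.comment_text, "sheetready")
            if cell.fill_color is not None:
                target.fill = PatternFill(
                    fill_type="solid",
                    start_color="FF" + cell.fill_color.lstrip("#"),
                )
            if cell.font_color is not None:
                target.font = Font(color="FF" + cell.font_color.lstrip("#"))
        for rect in sheet.merged_ranges:
            ws.merge_cells(
                start_row=rect.top,
                start_column=rect.left,
                end_row=rect.bottom,
                end_column=rect.right,
            )
        for obj in sheet.embedded_objects:
            _write_object(ws, obj)
    props = wb.doc_properties
    book.properties.creator = props.get("author")
    book.properties.title = props.get("title")
    return book


def _write_object(ws, obj: EmbeddedObject) -> None:
    anchor_ref = f"{get_column_letter(obj.anchor.column)}{obj.anchor.row}"
    if obj.kind is ObjectKind.CHART:
        from openpyxl.chart import BarChart, Reference

        chart = BarChart()
        chart.add_data(Reference(ws, min_col=1, min_row=1, max_row=2))
        ws.add_chart(chart, anchor_ref)
    elif obj.kind is ObjectKind.PICTURE:
        from openpyxl.drawing.image import Image
        from PIL import Image as PILImage

        buf = _io.BytesIO()
        PILImage.new("RGB", (4, 4), "#888888").save(buf, format="PNG")
        buf.seek(0)
        image = Image(buf)
        ws.add_image(image, anchor_ref)
    else:
        raise FormatError(
            "pivot tables cannot be serialised to .xlsx; "
            f"found one anchored at {obj.anchor}"
        )


# ---------------------------------------------------------------------------
# CSV reading

def _read_csv(path: Path) -> Workbook:
    try:
        data = path.read_bytes()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    try:
        text = data.decode("utf-8-sig")
    except UnicodeDecodeError:
        text = data.decode("latin-1")

    sheet = Sheet(name=path.stem)
    reader = csv.reader(_io.StringIO(text, newline=""))
    try:
        for r, record in enumerate(reader, start=1):
            for c, field in enumerate(record, start=1):
                value = sniff_csv_value(field)
                if value is not None:
                    sheet.set_value(r, c, value)
    except csv.Error as exc:
        raise FormatError(f"malformed CSV in {path}: {exc}") from exc

    model = Workbook(
        sheets=[sheet],
        source_path=str(path),
        source_format=SourceFormat.CSV,
    )
    model.validate()
    return model
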