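"""Deterministic fixture workbooks with injectable, bookkept defects.

``generate_fixture(defects, seed)`` builds a single-region table (unique
text header; text, number and date columns) and injects each requested
defect at recorded locations.  The returned bookkeeping maps each
injected rule id to exactly the locations the checker is expected to
report — that equality is the checker's principal test.

Injections are pairwise independent by construction: injecting one rule
never triggers another.  Two constructions need care and are documented
inline: ``multiple_sheets`` adds a second sheet that must itself be
pristine, and ``non_contiguous`` adds a second table that must carry its
own proper header.  Seeded randomness affects filler values only, never
structure.
"""

from __future__ import annotations

import datetime as _dt
import random
from typing import Sequence

from .errors import SheetReadyError
from .model import (
    CellAddress,
    EmbeddedObject,
    ObjectKind,
    Rect,
    Sheet,
    SourceFormat,
    Workbook,
)
from .checks import RULE_IDS

__all__ = ["generate_fixture", "Bookkeeping"]

Bookkeeping = dict[str, list]

_SHEET = "data"
_N_DATA_ROWS = 8  # data body rows 2..9
_BOTTOM = 1 + _N_DATA_ROWS


def generate_fixture(
    defects: Sequence[str] = (), seed: int = 0
) -> tuple[Workbook, Bookkeeping]:
    """Build a fixture workbook injecting ``defects``; see module docs."""
    defects = list(defects)
    unknown = [d for d in defects if d not in RULE_IDS]
    if unknown:
        raise SheetReadyError(
            f"unknown defect ids: {unknown}; valid ids: {list(RULE_IDS)}"
        )
    rng = random.Random(seed)

    sheet = Sheet(name=_SHEET)
    for col, label in enumerate(("site", "reading", "sampled"), start=1):
        sheet.set_value(1, col, label)
    base_date = _dt.date(2011, 8, 1)
    for i in range(_N_DATA_ROWS):
        row = 2 + i
        sheet.set_value(row, 1, f"site_{i + 1:02d}")
        sheet.set_value(row, 2, round(rng.uniform(0.0, 100.0), 2))
        sheet.set_value(row, 3, base_date + _dt.timedelta(days=i))

    wb = Workbook(
        sheets=[sheet],
        doc_properties={"author": "Avery Doe", "title": "Fixture dataset"},
        source_path="fixture.xlsx",
        source_format=SourceFormat.XLSX,
    )
    expected: Bookkeeping = {}

    # The header defect stacks a second all-text row on the table, so the
    # data body starts one row lower; region-scoped expectations track it.
    data_top = 3 if "header_problem" in defects else 2

    if "header_problem" in defects:
        for col, label in enumerate(("unit", "degC", "day"), start=1):
            sheet.set_value(2, col, label)
        expected["header_problem"] = [Rect(1, 1, 2, 3)]

    if "embedded_objects" in defects:
        anchor = CellAddress(_SHEET, 2, 5)
        sheet.embedded_objects.append(EmbeddedObject(ObjectKind.CHART, anchor))
        expected["embedded_objects"] = [anchor]

    if "embedded_comments" in defects:
        cell = sheet.cell_at(5, 2)
        cell.comment_text = "checked twice"
        expected["embedded_comments"] = [cell.address]

    if "commas" in defects:
        cell = sheet.set_value(5, 1, "Oakland, CA")
        expected["commas"] = [cell.address]

    if "special_characters" in defects:
        cell = sheet.set_value(6, 1, "µg/L")
        expected["special_characters"] = [cell.address]

    if "color_coding" in defects:
        cell = sheet.cell_at(6, 2)
        cell.fill_color = "#FFFF00"
        expected["color_coding"] = [cell.address]

    if "mixed_types" in defects:
        sheet.set_value(4, 2, "n/a")
        expected["mixed_types"] = [Rect(data_top, 2, _BOTTOM, 2)]

    if "blank_cells" in defects:
        sheet.clear_value(7, 2)
        expected["blank_cells"] = [CellAddress(_SHEET, 7, 2)]

    if "merged_cells" in defects:
        # merged range of empty cells below the table: flagged by rule 8
        # without creating cells that would disturb region detection
        rect = Rect(_BOTTOM + 1, 6, _BOTTOM + 2, 7)
        sheet.merged_ranges.append(rect)
        expected["merged_cells"] = [rect]

    if "non_contiguous" in defects:
        # second table across an empty separator column; it carries its
        # own unique text header so it adds no header_problem finding
        _small_table(sheet, top=1, left=5, rng=rng)
        expected["non_contiguous"] = [
            Rect(1, 1, _BOTTOM, 3),
            Rect(1, 5, 4, 6),
        ]

    if "multiple_sheets" in defects:
        # the second sheet must itself be pristine: single region,
        # proper header, homogeneous typed columns
        extra = Sheet(name="notes")
        _small_table(extra, top=1, left=1, rng=rng)
        wb.sheets.append(extra)
        expected["multiple_sheets"] = [_SHEET, "notes"]

    wb.validate()
    return wb, expected


def _small_table(sheet: Sheet, top: int, left: int, rng: random.Random):
    sheet.set_value(top, left, "plot")
    sheet.set_value(top, left + 1, "area")
    for i in range(3):
        sheet.set_value(top + 1 + i, left, f"plot_{i + 1}")
        sheet.set_value(top + 1 + i, left + 1, round(rng.uniform(1, 50), 1))
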