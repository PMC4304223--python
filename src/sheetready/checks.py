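"""The 11-rule best-practices checker.

Each rule evaluates one way a spreadsheet can fail to be CSV-compatible or
machine-readable, reports the locations involved, and carries the
published *why* and *suggested remedy* texts so reports can explain
themselves.  Rules 3–6 and 9 are scoped to detected table regions;
rules 1, 2, 8 and 11 are workbook/sheet-global.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Optional

from .model import CellAddress, Location, Rect, Sheet, ValueKind, Workbook
from .regions import TableRegion, detect_regions
from .errors import SheetReadyError

__all__ = [
    "RULE_IDS",
    "RuleDescriptor",
    "Issue",
    "CheckReport",
    "rule_catalogue",
    "run_all_checks",
    "render_report",
]

#: The closed set of rule identifiers, in catalogue order 1–11.
RULE_IDS = (
    "embedded_objects",
    "embedded_comments",
    "commas",
    "special_characters",
    "color_coding",
    "mixed_types",
    "non_contiguous",
    "merged_cells",
    "blank_cells",
    "header_problem",
    "multiple_sheets",
)

#: Characters admitted by the special-characters rule (rule 4).  The
#: published guidance says only "use alpha-numeric characters only";
#: period, underscore, hyphen, parentheses and slash are additionally
#: admitted here as archival-safe.  The comma is owned by rule 3 and is
#: deliberately excluded from this rule's jurisdiction.
ALLOWED_CHARACTERS = frozenset(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    "abcdefghijklmnopqrstuvwxyz"
    "0123456789"
    " ._-()/"
    ","  # never flagged here; rule 3 territory
)


@dataclass(frozen=True)
class RuleDescriptor:
    rule_id: str
    number: int
    title: str
    why_text: str
    remedy_text: str
    auto_fixable: bool
    severity: str  # "warning" | "info"


_CATALOGUE = (
    RuleDescriptor(
        "embedded_objects",
        1,
        "Embedded charts, tables, pictures.",
        "These embedded items will not be visible when data are exported "
        "as a .csv file. Also, these elements are visible only if the file "
        "is opened with Microsoft Excel.",
        "Move embedded charts, tables, or pictures to other tabs in your "
        "file or to a completely separate file.",
        True,
        "warning",
    ),
    RuleDescriptor(
        "embedded_comments",
        2,
        "Embedded comments.",
        "Comments will not be visible when data are exported as a .csv "
        "file. Also, these elements are visible only if the file is opened "
        "with Microsoft Excel.",
        "Create a new column titled “Comments” and add your text "
        "there.",
        True,
        "warning",
    ),
    RuleDescriptor(
        "commas",
        3,
        "Commas.",
        "Commas are often used to separate multiple piece of "
        "information/data (e.g. City, State). Cells only contain one piece "
        "of information.",
        "Split pieces of information into multiple columns (e.g. City "
        "column and State column).",
        False,
        "warning",
    ),
    RuleDescriptor(
        "special_characters",
        4,
        "Special characters.",
        "Special characters may cause problems for other programs or may "
        "be modified upon export.",
        "Use alpha-numeric characters only. If needed, describe the symbol "
        "in a new column.",
        False,
        "warning",
    ),
    RuleDescriptor(
        "color_coding",
        5,
        "Color coded text or cell shading.",
        "Formatting will not be visible when data are exported as a .csv "
        "file. If formatting is used as a coding scheme, all codes will be "
        "lost upon export.",
        "Use descriptions or alphanumeric coding schemes in a new column.",
        True,
        "warning",
    ),
    RuleDescriptor(
        "mixed_types",
        6,
        "Columns have mixed data types.",
        "Some programs cannot handle mixed data types (e.g. numbers and "
        "text in the same column).",
        "Ensure you are using only numbers or only text in a column; split "
        "data into multiple columns if necessary.",
        False,
        "warning",
    ),
    RuleDescriptor(
        "non_contiguous",
        7,
        "Non-contiguous data.",
        "Empty columns or rows tend to be used to separate multiple data "
        "tables on the same tab.",
        "Move multiple tables onto separate tabs.",
        False,
        "warning",
    ),
    RuleDescriptor(
        "merged_cells",
        8,
        "Merged cells.",
        "Merged cells will not be maintained when data are exported as a "
        ".csv file. Information may be lost when cells are un-merged upon "
        "export.",
        "Un-merge cells and annotate appropriately so information is not "
        "lost.",
        True,
        "warning",
    ),
    RuleDescriptor(
        "blank_cells",
        9,
        "Blank cells.",
        "Blank cells within a contiguous data table are potentially "
        "problematic for reading files in other programs.",
        "Designate a coding scheme for missing data or other explanations "
        "for blank cells.",
        False,
        "warning",
    ),
    RuleDescriptor(
        "header_problem",
        10,
        "Header row absent or more than one header row.",
        "Ideally the first row of a data table contains parameter names "
        "for the columns. If there is no header row, your data table may "
        "be difficult to use and document. If there are multiple header "
        "rows, some software programs may have problems.",
        "Create a header row with unique parameter names that describe the "
        "column’s contents.",
        False,
        "warning",
    ),
    RuleDescriptor(
        "multiple_sheets",
        11,
        "Multiple sheets (tabs).",
        "Multiple sheets will not be maintained as a single document if "
        "the file is converted to .csv.",
        "The user can move each tab into a separate .csv file. If left as "
        "multiple sheets, the DataUp tool will automatically export the "
        "data as separate .csv files.",
        True,
        "info",
    ),
)

_BY_ID = {d.rule_id: d for d in _CATALOGUE}


def rule_catalogue() -> tuple[RuleDescriptor, ...]:
    """The closed, ordered 11-rule catalogue."""
    return _CATALOGUE


@dataclass
class Issue:
    """One located finding; locations aggregate per (rule, sheet)."""

    rule_id: str
    sheet_name: Optional[str]
    locations: list[Location] = field(default_factory=list)
    detail: str = ""
    sheet_names: Optional[list[str]] = None  # multiple_sheets only

    def __post_init__(self):
        if self.rule_id not in _BY_ID:
            raise SheetReadyError(f"unknown rule id: {self.rule_id}")

    @property
    def descriptor(self) -> RuleDescriptor:
        return _BY_ID[self.rule_id]

    @property
    def why_text(self) -> str:
        return self.descriptor.why_text

    @property
    def remedy_text(self) -> str:
        return self.descriptor.remedy_text

    @property
    def auto_fixable(self) -> bool:
        return self.descriptor.auto_fixable

    @property
    def severity(self) -> str:
        return self.descriptor.severity


@dataclass
class CheckReport:
    source: str
    checked_at: str
    issues: list[Issue]

    @property
    def passed(self) -> bool:
        return not self.issues

    @property
    def per_rule_counts(self) -> dict[str, int]:
        counts = {rule_id: 0 for rule_id in RULE_IDS}
        for issue in self.issues:
            counts[issue.rule_id] += 1
        return counts


RegionMap = dict[str, list[TableRegion]]


def _regions_for(wb: Workbook) -> RegionMap:
    return {sheet.name: detect_regions(sheet) for sheet in wb.sheets}


# ---------------------------------------------------------------------------
# individual rules


def check_embedded_objects(wb: Workbook) -> list[Issue]:
    """Rule 1: charts, pictures and pivot tables, one issue per sheet."""
    issues = []
    for sheet in wb.sheets:
        if sheet.embedded_objects:
            issues.append(
                Issue(
                    "embedded_objects",
                    sheet.name,
                    [obj.anchor for obj in sheet.embedded_objects],
                    detail=", ".join(
                        f"{o.kind.value} at {o.anchor.a1}"
                        for o in sheet.embedded_objects
                    ),
                )
            )
    return issues


def check_embedded_comments(wb: Workbook) -> list[Issue]:
    """Rule 2: every commented cell, including comments on empty cells."""
    issues = []
    for sheet in wb.sheets:
        located = [
            cell.address
            for _, cell in sorted(sheet.cells.items())
            if cell.comment_text is not None
        ]
        if located:
            issues.append(Issue("embedded_comments", sheet.name, located))
    return issues


def check_commas(wb: Workbook, regions: RegionMap) -> list[Issue]:
    """Rule 3: text cells inside regions containing a comma."""
    return _scan_region_text(
        wb, regions, "commas", lambda text: "," in text, include_header=True
    )


def check_special_characters(wb: Workbook, regions: RegionMap) -> list[Issue]:
    """Rule 4: text cells with characters outside the allowed set."""
    return _scan_region_text(
        wb,
        regions,
        "special_characters",
        lambda text: any(ch not in ALLOWED_CHARACTERS for ch in text),
        include_header=True,
    )


def _scan_region_text(wb, regions, rule_id, predicate, include_header):
    issues = []
    for sheet in wb.sheets:
        located = []
        for region in regions.get(sheet.name, []):
            top = (
                region.bounds.top
                if include_header
                else region.data_top
            )
            for row in range(top, region.bounds.bottom + 1):
                for col in range(region.bounds.left, region.bounds.right + 1):
                    cell = sheet.cell_at(row, col)
                    if (
                        cell is not None
                        and cell.value_kind is ValueKind.TEXT
                        and predicate(cell.raw_value)
                    ):
                        located.append(cell.address)
        if located:
            issues.append(Issue(rule_id, sheet.name, located))
    return issues


def check_color_coding(wb: Workbook, regions: RegionMap) -> list[Issue]:
    """Rule 5: region cells with an explicit fill or font color."""
    issues = []
    for sheet in wb.sheets:
        located = []
        for region in regions.get(sheet.name, []):
            for row in range(region.bounds.top, region.bounds.bottom + 1):
                for col in range(region.bounds.left, region.bounds.right + 1):
                    cell = sheet.cell_at(row, col)
                    if cell is not None and (
                        cell.fill_color is not None
                        or cell.font_color is not None
                    ):
                        located.append(cell.address)
        if located:
            issues.append(Issue("color_coding", sheet.name, located))
    return issues


def check_mixed_types(wb: Workbook, regions: RegionMap) -> list[Issue]:
    """Rule 6: region columns mixing kinds below the header rows."""
    issues = []
    for sheet in wb.sheets:
        located = []
        details = []
        for region in regions.get(sheet.name, []):
            data_top = region.data_top
            if data_top > region.bounds.bottom:
                continue
            for col in range(region.bounds.left, region.bounds.right + 1):
                kinds = {
                    sheet.kind_at(row, col)
                    for row in range(data_top, region.bounds.bottom + 1)
                }
                kinds &= {
                    ValueKind.NUMBER,
                    ValueKind.TEXT,
                    ValueKind.DATE,
                    ValueKind.BOOLEAN,
                }
                if len(kinds) >= 2:
                    located.append(
                        Rect(data_top, col, region.bounds.bottom, col)
                    )
                    details.append(
                        "column contains "
                        + " and ".join(sorted(k.value for k in kinds))
                    )
        if located:
            issues.append(
                Issue(
                    "mixed_types",
                    sheet.name,
                    located,
                    detail="; ".join(details),
                )
            )
    return issues


def check_non_contiguous(wb: Workbook, regions: RegionMap) -> list[Issue]:
    """Rule 7: sheets carrying more than one table region."""
    issues = []
    for sheet in wb.sheets:
        sheet_regions = regions.get(sheet.name, [])
        if len(sheet_regions) >= 2:
            issues.append(
                Issue(
                    "non_contiguous",
                    sheet.name,
                    [region.bounds for region in sheet_regions],
                )
            )
    return issues


def check_merged_cells(wb: Workbook) -> list[Issue]:
    """Rule 8: every merged range."""
    issues = []
    for sheet in wb.sheets:
        if sheet.merged_ranges:
            issues.append(
                Issue(
                    "merged_cells",
                    sheet.name,
                    sorted(sheet.merged_ranges),
                )
            )
    return issues


def check_blank_cells(wb: Workbook, regions: RegionMap) -> list[Issue]:
    """Rule 9: empty cells inside a region's bounds (true gaps)."""
    issues = []
    for sheet in wb.sheets:
        located = []
        for region in regions.get(sheet.name, []):
            for row, col in region.bounds.cells():
                if sheet.is_blank(row, col):
                    located.append(CellAddress(sheet.name, row, col))
        if located:
            issues.append(Issue("blank_cells", sheet.name, located))
    return issues


def check_header(wb: Workbook, regions: RegionMap) -> list[Issue]:
    """Rule 10: header absent, duplicated labels, or stacked headers."""
    issues = []
    for sheet in wb.sheets:
        located = []
        details = []
        for region in regions.get(sheet.name, []):
            bounds = region.bounds
            if region.header_row_count == 0:
                top_row = [
                    sheet.cell_at(bounds.top, c)
                    for c in range(bounds.left, bounds.right + 1)
                ]
                all_text = all(
                    c is not None and c.value_kind is ValueKind.TEXT
                    for c in top_row
                )
                if all_text:
                    labels = [c.raw_value for c in top_row]
                    dupes = sorted(
                        {x for x in labels if labels.count(x) > 1}
                    )
                    details.append(
                        "duplicate header labels: " + ", ".join(dupes)
                    )
                else:
                    details.append("header row absent")
                located.append(
                    Rect(bounds.top, bounds.left, bounds.top, bounds.right)
                )
            elif region.header_row_count >= 2:
                details.append(
                    f"{region.header_row_count} stacked header rows"
                )
                located.append(
                    Rect(
                        bounds.top,
                        bounds.left,
                        bounds.top + region.header_row_count - 1,
                        bounds.right,
                    )
                )
        if located:
            issues.append(
                Issue(
                    "header_problem",
                    sheet.name,
                    located,
                    detail="; ".join(details),
                )
            )
    return issues


def check_multiple_sheets(wb: Workbook) -> list[Issue]:
    """Rule 11 (informational): more than one non-empty sheet."""
    non_empty = [s.name for s in wb.sheets if not s.is_empty]
    if len(non_empty) <= 1:
        return []
    return [
        Issue(
            "multiple_sheets",
            None,
            [],
            detail="sheets: " + ", ".join(non_empty),
            sheet_names=non_empty,
        )
    ]


# ---------------------------------------------------------------------------
# driver and rendering


def run_all_checks(wb: Workbook) -> CheckReport:
    """Run all 11 rules in catalogue order; deterministic per workbook."""
    regions = _regions_for(wb)
    issues: list[Issue] = []
    issues += check_embedded_objects(wb)
    issues += check_embedded_comments(wb)
    issues += check_commas(wb, regions)
    issues += check_special_characters(wb, regions)
    issues += check_color_coding(wb, regions)
    issues += check_mixed_types(wb, regions)
    issues += check_non_contiguous(wb, regions)
    issues += check_merged_cells(wb)
    issues += check_blank_cells(wb, regions)
    issues += check_header(wb, regions)
    issues += check_multiple_sheets(wb)
    order = {rule_id: i for i, rule_id in enumerate(RULE_IDS)}
    issues.sort(key=lambda iss: (order[iss.rule_id], iss.sheet_name or ""))
    return CheckReport(
        source=wb.source_path or "<in-memory workbook>",
        checked_at=_dt.datetime.now().isoformat(timespec="seconds"),
        issues=issues,
    )


def _location_str(loc: Location) -> str:
    return loc.a1


def report_to_dict(report: CheckReport) -> dict:
    return {
        "source": report.source,
        "checked_at": report.checked_at,
        "passed": report.passed,
        "per_rule_counts": report.per_rule_counts,
        "issues": [
            {
                "rule_id": issue.rule_id,
                "rule_number": issue.descriptor.number,
                "title": issue.descriptor.title,
                "sheet": issue.sheet_name,
                "locations": [_location_str(l) for l in issue.locations],
                "why": issue.why_text,
                "remedy": issue.remedy_text,
                "auto_fixable": issue.auto_fixable,
                "severity": issue.severity,
                "detail": issue.detail,
                "sheet_names": issue.sheet_names,
            }
            for issue in report.issues
        ],
    }


def render_report(report: CheckReport, fmt: str = "text") -> str:
    """Render a report as human-readable text or stable JSON."""
    if fmt == "json":
        return json.dumps(report_to_dict(report), indent=2) + "\n"
    if fmt != "text":
        raise SheetReadyError(
            f"unknown report format {fmt!r}; expected 'text' or 'json'"
        )
    lines = [
        f"Best practices check: {report.source}",
        f"Checked at: {report.checked_at}",
        f"Result: {len(report.issues)} issues"
        + (" — PASSED" if report.passed else ""),
        "",
    ]
    for issue in report.issues:
        d = issue.descriptor
        where = f" [{issue.sheet_name}]" if issue.sheet_name else ""
        lines.append(f"{d.number}. {d.title}{where} ({issue.severity})")
        if issue.locations:
            lines.append(
                "   Locations: "
                + ", ".join(_location_str(l) for l in issue.locations)
            )
        if issue.detail:
            lines.append(f"   Detail: {issue.detail}")
        lines.append(f"   Why: {d.why_text}")
        lines.append(f"   Suggested remedy: {d.remedy_text}")
        lines.append("")
    return "\n".join(lines)
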