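"""Dataset metadata: the 47-element schema, validation, EML serialisation,
and spreadsheet-tab embedding.

The schema holds 42 file-level elements in three groups (basic
information, personnel, dataset) plus 5 column-level parameter elements,
with 7 elements required.  Completeness is exactly the predicate "all 7
required elements are non-empty".

EML output targets the EML 2.1.1 element vocabulary.  Full XSD validation
is deliberately not performed; the contract is well-formedness plus a
lossless serialise→parse round-trip of every populated field.
"""

from __future__ import annotations

import datetime as _dt
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .errors import (
    HeaderAbsentError,
    MetadataValidationError,
    SheetReadyError,
)
from .model import Sheet, ValueKind, Workbook
from .regions import TableRegion

__all__ = [
    "ElementDescriptor",
    "FileMetadata",
    "AttributeMetadata",
    "MetadataRecord",
    "schema_elements",
    "required_elements",
    "prepopulate",
    "attributes_from_header",
    "validate",
    "to_eml",
    "from_eml",
    "embed_metadata_sheet",
    "extract_metadata_sheet",
]

EML_NS = "eml://ecoinformatics.org/eml-2.1.1"


@dataclass(frozen=True)
class ElementDescriptor:
    key: str          # stable machine key (FileMetadata field name)
    name: str         # display name
    group: str        # basic | personnel | dataset | parameter
    required: bool


def _person_elements(prefix: str, label: str) -> list[ElementDescriptor]:
    required = {"first_name", "last_name", "email"} if prefix == "creator" else set()
    parts = [
        ("first_name", "First name"),
        ("last_name", "Last name"),
        ("organization", "Organization"),
        ("address", "Address"),
        ("city", "City"),
        ("state", "State/province"),
        ("postal_code", "Postal code"),
        ("country", "Country"),
        ("phone", "Phone"),
        ("email", "Email"),
    ]
    return [
        ElementDescriptor(
            f"{prefix}_{key}", f"{label}: {name}", "personnel", key in required
        )
        for key, name in parts
    ]


_SCHEMA: tuple[ElementDescriptor, ...] = tuple(
    [
        ElementDescriptor("today_date", "Today's date", "basic", True),
        ElementDescriptor("dataset_title", "Title of dataset", "basic", True),
        ElementDescriptor("abstract", "Abstract", "basic", True),
        ElementDescriptor("keywords", "Keyword(s)", "basic", True),
        ElementDescriptor(
            "keyword_thesaurus", "Keyword thesaurus used", "basic", False
        ),
        ElementDescriptor("identifier", "Identifier", "basic", False),
        ElementDescriptor(
            "formatted_citation", "Formatted citation", "basic", False
        ),
    ]
    + _person_elements("creator", "Creator")
    + _person_elements("contact", "Data Contact Person")
    + [
        ElementDescriptor(
            "temporal_begin", "Temporal coverage: Beginning date",
            "dataset", False,
        ),
        ElementDescriptor(
            "temporal_end", "Temporal coverage: Ending date",
            "dataset", False,
        ),
        ElementDescriptor(
            "geographic_description", "Geographic coverage: Description",
            "dataset", False,
        ),
        ElementDescriptor(
            "west_bounding", "West bounding coordinate", "dataset", False
        ),
        ElementDescriptor(
            "east_bounding", "East bounding coordinate", "dataset", False
        ),
        ElementDescriptor(
            "north_bounding", "North bounding coordinate", "dataset", False
        ),
        ElementDescriptor(
            "south_bounding", "South bounding coordinate", "dataset", False
        ),
        ElementDescriptor(
            "intellectual_rights", "Intellectual rights", "dataset", False
        ),
        ElementDescriptor("project_title", "Project title", "dataset", False),
        ElementDescriptor(
            "project_description", "Project description", "dataset", False
        ),
        ElementDescriptor(
            "project_personnel", "Project personnel", "dataset", False
        ),
        ElementDescriptor(
            "project_personnel_role", "Project personnel role",
            "dataset", False,
        ),
        ElementDescriptor(
            "publisher", "Data Publisher: repository name", "dataset", False
        ),
        ElementDescriptor(
            "data_table_name", "Data table name", "dataset", False
        ),
        ElementDescriptor(
            "data_table_description", "Data table description",
            "dataset", False,
        ),
        # column-level parameter (attribute) elements
        ElementDescriptor("parameter_name", "Parameter name", "parameter", False),
        ElementDescriptor(
            "parameter_label", "Parameter label", "parameter", False
        ),
        ElementDescriptor(
            "parameter_definition", "Parameter definition", "parameter", False
        ),
        ElementDescriptor(
            "parameter_units", "Parameter units", "parameter", False
        ),
        ElementDescriptor(
            "parameter_measurement_scale", "Parameter measurement scale",
            "parameter", False,
        ),
    ]
)


def schema_elements() -> tuple[ElementDescriptor, ...]:
    """The full, ordered metadata schema: 47 elements, 7 required."""
    return _SCHEMA


def required_elements() -> tuple[ElementDescriptor, ...]:
    return tuple(d for d in _SCHEMA if d.required)


_FILE_LEVEL_KEYS = tuple(d.key for d in _SCHEMA if d.group != "parameter")


@dataclass
class FileMetadata:
    """The 42 file-level elements; empty string / empty list = unset."""

    today_date: str = ""
    dataset_title: str = ""
    abstract: str = ""
    keywords: list[str] = field(default_factory=list)
    keyword_thesaurus: str = ""
    identifier: str = ""
    formatted_citation: str = ""

    creator_first_name: str = ""
    creator_last_name: str = ""
    creator_organization: str = ""
    creator_address: str = ""
    creator_city: str = ""
    creator_state: str = ""
    creator_postal_code: str = ""
    creator_country: str = ""
    creator_phone: str = ""
    creator_email: str = ""

    contact_first_name: str = ""
    contact_last_name: str = ""
    contact_organization: str = ""
    contact_address: str = ""
    contact_city: str = ""
    contact_state: str = ""
    contact_postal_code: str = ""
    contact_country: str = ""
    contact_phone: str = ""
    contact_email: str = ""

    temporal_begin: str = ""
    temporal_end: str = ""
    geographic_description: str = ""
    west_bounding: str = ""
    east_bounding: str = ""
    north_bounding: str = ""
    south_bounding: str = ""
    intellectual_rights: str = ""
    project_title: str = ""
    project_description: str = ""
    project_personnel: str = ""
    project_personnel_role: str = ""
    publisher: str = ""
    data_table_name: str = ""
    data_table_description: str = ""

    def get(self, key: str) -> Union[str, list[str]]:
        return getattr(self, key)

    def set(self, key: str, value: Union[str, list[str]]) -> None:
        if key not in _FILE_LEVEL_KEYS:
            raise SheetReadyError(f"unknown metadata element key: {key}")
        if key == "keywords" and isinstance(value, str):
            value = [k.strip() for k in value.split(";") if k.strip()]
        setattr(self, key, value)

    def is_set(self, key: str) -> bool:
        value = getattr(self, key)
        return bool(value)


@dataclass
class AttributeMetadata:
    """Column-level (parameter) metadata for one data-table column."""

    parameter_name: str
    column_index: int
    definition: str = ""
    units: str = ""
    label: str = ""
    measurement_scale: str = ""


@dataclass
class MetadataRecord:
    file_level: FileMetadata = field(default_factory=FileMetadata)
    attributes: list[AttributeMetadata] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        """True iff all 7 required elements are non-empty."""
        return all(
            self.file_level.is_set(d.key) for d in required_elements()
        )


# ---------------------------------------------------------------------------
# pre-population and attribute stubs


def prepopulate(wb: Workbook) -> FileMetadata:
    """Seed a file-level record from workbook document properties."""
    md = FileMetadata()
    md.today_date = _dt.date.today().isoformat()
    author = wb.doc_properties.get("author", "").strip()
    if author:
        head, _, tail = author.rpartition(" ")
        if head:
            md.creator_first_name, md.creator_last_name = head, tail
        else:
            md.creator_last_name = tail
    title = wb.doc_properties.get("title", "").strip()
    if title:
        md.dataset_title = title
    elif wb.source_path:
        md.dataset_title = Path(wb.source_path).stem
    return md


def attributes_from_header(
    region: TableRegion, sheet: Sheet
) -> list[AttributeMetadata]:
    """One parameter stub per column, named from the region's header row."""
    if region.header_row is None or region.header_row_count == 0:
        raise HeaderAbsentError(
            f"region {region.bounds.a1} on sheet {sheet.name!r} has no "
            "header row; create a header row with unique parameter names "
            "that describe the column's contents, then retry"
        )
    stubs = []
    for col in range(region.bounds.left, region.bounds.right + 1):
        cell = sheet.cell_at(region.header_row, col)
        name = str(cell.raw_value) if cell is not None else ""
        stubs.append(AttributeMetadata(parameter_name=name, column_index=col))
    return stubs


# ---------------------------------------------------------------------------
# validation

_ISO_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


def _check_date(value: str, name: str, findings: list[str]) -> None:
    if not value:
        return
    if not _ISO_DATE_RE.match(value):
        findings.append(f"{name} is not an ISO 8601 date: {value!r}")
        return
    try:
        _dt.date.fromisoformat(value)
    except ValueError:
        findings.append(f"{name} is not a valid date: {value!r}")


def _coord(value: str, name: str, findings: list[str]) -> Optional[float]:
    if not value:
        return None
    try:
        return float(value)
    except ValueError:
        findings.append(f"{name} is not numeric: {value!r}")
        return None


def validate(md: MetadataRecord) -> list[str]:
    """Return findings; empty list ⇔ complete and internally consistent."""
    findings: list[str] = []
    fl = md.file_level
    for d in required_elements():
        if not fl.is_set(d.key):
            findings.append(f"Required element missing: {d.name}")

    _check_date(fl.today_date, "Today's date", findings)
    _check_date(fl.temporal_begin, "Temporal coverage: Beginning date", findings)
    _check_date(fl.temporal_end, "Temporal coverage: Ending date", findings)

    south = _coord(fl.south_bounding, "South bounding coordinate", findings)
    north = _coord(fl.north_bounding, "North bounding coordinate", findings)
    west = _coord(fl.west_bounding, "West bounding coordinate", findings)
    east = _coord(fl.east_bounding, "East bounding coordinate", findings)
    for val, name in ((south, "South"), (north, "North")):
        if val is not None and not -90 <= val <= 90:
            findings.append(
                f"{name} bounding coordinate out of range [-90, 90]: {val}"
            )
    for val, name in ((west, "West"), (east, "East")):
        if val is not None and not -180 <= val <= 180:
            findings.append(
                f"{name} bounding coordinate out of range [-180, 180]: {val}"
            )
    if south is not None and north is not None and south > north:
        findings.append(
            "South bounding coordinate exceeds North bounding coordinate"
        )

    for key, name in (
        ("creator_email", "Creator: Email"),
        ("contact_email", "Data Contact Person: Email"),
    ):
        value = fl.get(key)
        if value and "@" not in value:
            findings.append(f"{name} does not look like an address: {value!r}")

    for i, attr in enumerate(md.attributes, start=1):
        if not attr.parameter_name:
            findings.append(f"Attribute {i} has an empty parameter name")
        if attr.column_index < 1:
            findings.append(
                f"Attribute {i} has an invalid column index: "
                f"{attr.column_index}"
            )
    return findings


# ---------------------------------------------------------------------------
# EML serialisation

ET.register_namespace("eml", EML_NS)


def _sub(parent, tag, text=""):
    el = ET.SubElement(parent, tag)
    if text:
        el.text = text
    return el


def _person(parent, tag, fl, prefix):
    get = lambda k: fl.get(f"{prefix}_{k}")
    el = ET.SubElement(parent, tag)
    if get("first_name") or get("last_name"):
        name = _sub(el, "individualName")
        if get("first_name"):
            _sub(name, "givenName", get("first_name"))
        if get("last_name"):
            _sub(name, "surName", get("last_name"))
    if get("organization"):
        _sub(el, "organizationName", get("organization"))
    addr_keys = ("address", "city", "state", "postal_code", "country")
    if any(get(k) for k in addr_keys):
        addr = _sub(el, "address")
        for key, tag2 in (
            ("address", "deliveryPoint"),
            ("city", "city"),
            ("state", "administrativeArea"),
            ("postal_code", "postalCode"),
            ("country", "country"),
        ):
            if get(key):
                _sub(addr, tag2, get(key))
    if get("phone"):
        _sub(el, "phone", get("phone"))
    if get("email"):
        _sub(el, "electronicMailAddress", get("email"))
    return el


def to_eml(md: MetadataRecord) -> str:
    """Serialise a valid record to an EML XML document (UTF-8 string)."""
    findings = validate(md)
    if findings:
        raise MetadataValidationError(findings)
    fl = md.file_level

    root = ET.Element(f"{{{EML_NS}}}eml")
    root.set("packageId", fl.identifier or "unassigned")
    root.set("system", "sheetready")
    ds = ET.SubElement(root, "dataset")

    if fl.identifier:
        _sub(ds, "alternateIdentifier", fl.identifier)
    _sub(ds, "title", fl.dataset_title)
    _person(ds, "creator", fl, "creator")
    _sub(ds, "pubDate", fl.today_date)
    _sub(_sub(ds, "abstract"), "para", fl.abstract)

    kws = ET.SubElement(ds, "keywordSet")
    for kw in fl.keywords:
        _sub(kws, "keyword", kw)
    if fl.keyword_thesaurus:
        _sub(kws, "keywordThesaurus", fl.keyword_thesaurus)

    if fl.formatted_citation:
        _sub(_sub(ds, "additionalInfo"), "para", fl.formatted_citation)
    if fl.intellectual_rights:
        _sub(_sub(ds, "intellectualRights"), "para", fl.intellectual_rights)

    cov_needed = any(
        (
            fl.geographic_description,
            fl.west_bounding,
            fl.east_bounding,
            fl.north_bounding,
            fl.south_bounding,
            fl.temporal_begin,
            fl.temporal_end,
        )
    )
    if cov_needed:
        cov = ET.SubElement(ds, "coverage")
        if fl.geographic_description or any(
            (fl.west_bounding, fl.east_bounding,
             fl.north_bounding, fl.south_bounding)
        ):
            geo = _sub(cov, "geographicCoverage")
            if fl.geographic_description:
                _sub(geo, "geographicDescription", fl.geographic_description)
            if any((fl.west_bounding, fl.east_bounding,
                    fl.north_bounding, fl.south_bounding)):
                box = _sub(geo, "boundingCoordinates")
                for key, tag in (
                    ("west_bounding", "westBoundingCoordinate"),
                    ("east_bounding", "eastBoundingCoordinate"),
                    ("north_bounding", "northBoundingCoordinate"),
                    ("south_bounding", "southBoundingCoordinate"),
                ):
                    if fl.get(key):
                        _sub(box, tag, fl.get(key))
        if fl.temporal_begin or fl.temporal_end:
            rng = _sub(_sub(cov, "temporalCoverage"), "rangeOfDates")
            if fl.temporal_begin:
                _sub(_sub(rng, "beginDate"), "calendarDate", fl.temporal_begin)
            if fl.temporal_end:
                _sub(_sub(rng, "endDate"), "calendarDate", fl.temporal_end)

    if fl.publisher:
        _sub(_sub(ds, "publisher"), "organizationName", fl.publisher)
    _person(ds, "contact", fl, "contact")

    if any((fl.project_title, fl.project_description,
            fl.project_personnel, fl.project_personnel_role)):
        proj = _sub(ds, "project")
        if fl.project_title:
            _sub(proj, "title", fl.project_title)
        if fl.project_personnel or fl.project_personnel_role:
            pers = _sub(proj, "personnel")
            if fl.project_personnel:
                _sub(_sub(pers, "individualName"), "surName",
                     fl.project_personnel)
            if fl.project_personnel_role:
                _sub(pers, "role", fl.project_personnel_role)
        if fl.project_description:
            _sub(_sub(proj, "abstract"), "para", fl.project_description)

    if md.attributes or fl.data_table_name or fl.data_table_description:
        table = _sub(ds, "dataTable")
        if fl.data_table_name:
            _sub(table, "entityName", fl.data_table_name)
        if fl.data_table_description:
            _sub(table, "entityDescription", fl.data_table_description)
        if md.attributes:
            attrs = _sub(table, "attributeList")
            for a in md.attributes:
                el = _sub(attrs, "attribute")
                el.set("columnIndex", str(a.column_index))
                _sub(el, "attributeName", a.parameter_name)
                if a.label:
                    _sub(el, "attributeLabel", a.label)
                if a.definition:
                    _sub(el, "attributeDefinition", a.definition)
                if a.units:
                    _sub(_sub(el, "measurementScale"), "unit", a.units)
                if a.measurement_scale:
                    _sub(el, "scaleType", a.measurement_scale)

    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def _text(el, path) -> str:
    found = el.find(path)
    return (found.text or "") if found is not None else ""


def _person_from(el, fl, prefix) -> None:
    if el is None:
        return
    mapping = {
        "first_name": "individualName/givenName",
        "last_name": "individualName/surName",
        "organization": "organizationName",
        "address": "address/deliveryPoint",
        "city": "address/city",
        "state": "address/administrativeArea",
        "postal_code": "address/postalCode",
        "country": "address/country",
        "phone": "phone",
        "email": "electronicMailAddress",
    }
    for key, path in mapping.items():
        value = _text(el, path)
        if value:
            fl.set(f"{prefix}_{key}", value)


def from_eml(document: Union[str, bytes]) -> MetadataRecord:
    """Parse an EML document produced by :func:`to_eml` back to a record."""
    root = ET.fromstring(document)
    ds = root.find("dataset")
    if ds is None:
        raise SheetReadyError("EML document has no dataset element")
    fl = FileMetadata()

    fl.identifier = _text(ds, "alternateIdentifier")
    fl.dataset_title = _text(ds, "title")
    fl.today_date = _text(ds, "pubDate")
    fl.abstract = _text(ds, "abstract/para")
    fl.keywords = [
        (kw.text or "") for kw in ds.findall("keywordSet/keyword")
    ]
    fl.keyword_thesaurus = _text(ds, "keywordSet/keywordThesaurus")
    fl.formatted_citation = _text(ds, "additionalInfo/para")
    fl.intellectual_rights = _text(ds, "intellectualRights/para")

    _person_from(ds.find("creator"), fl, "creator")
    _person_from(ds.find("contact"), fl, "contact")

    geo = "coverage/geographicCoverage/"
    fl.geographic_description = _text(ds, geo + "geographicDescription")
    fl.west_bounding = _text(
        ds, geo + "boundingCoordinates/westBoundingCoordinate")
    fl.east_bounding = _text(
        ds, geo + "boundingCoordinates/eastBoundingCoordinate")
    fl.north_bounding = _text(
        ds, geo + "boundingCoordinates/northBoundingCoordinate")
    fl.south_bounding = _text(
        ds, geo + "boundingCoordinates/southBoundingCoordinate")
    rng = "coverage/temporalCoverage/rangeOfDates/"
    fl.temporal_begin = _text(ds, rng + "beginDate/calendarDate")
    fl.temporal_end = _text(ds, rng + "endDate/calendarDate")

    fl.publisher = _text(ds, "publisher/organizationName")
    fl.project_title = _text(ds, "project/title")
    fl.project_description = _text(ds, "project/abstract/para")
    fl.project_personnel = _text(
        ds, "project/personnel/individualName/surName")
    fl.project_personnel_role = _text(ds, "project/personnel/role")
    fl.data_table_name = _text(ds, "dataTable/entityName")
    fl.data_table_description = _text(ds, "dataTable/entityDescription")

    attributes = []
    for el in ds.findall("dataTable/attributeList/attribute"):
        attributes.append(
            AttributeMetadata(
                parameter_name=_text(el, "attributeName"),
                column_index=int(el.get("columnIndex", "0") or 0),
                definition=_text(el, "attributeDefinition"),
                units=_text(el, "measurementScale/unit"),
                label=_text(el, "attributeLabel"),
                measurement_scale=_text(el, "scaleType"),
            )
        )
    return MetadataRecord(file_level=fl, attributes=attributes)


# ---------------------------------------------------------------------------
# spreadsheet-tab embedding

METADATA_SHEET_NAME = "Metadata"

_ATTR_ROW_KEYS = (
    ("Parameter name", "parameter_name"),
    ("Parameter label", "label"),
    ("Parameter definition", "definition"),
    ("Parameter units", "units"),
    ("Parameter measurement scale", "measurement_scale"),
    ("Column index", "column_index"),
)


def embed_metadata_sheet(wb: Workbook, md: MetadataRecord) -> Workbook:
    """Append (or replace) a "Metadata" sheet of element-name/value rows."""
    out = wb.copy()
    out.sheets = [s for s in out.sheets if s.name != METADATA_SHEET_NAME]
    sheet = Sheet(name=METADATA_SHEET_NAME)
    row = 1
    for d in _SCHEMA:
        if d.group == "parameter":
            continue
        value = md.file_level.get(d.key)
        if d.key == "keywords":
            value = "; ".join(value)
        sheet.set_value(row, 1, d.name, kind=ValueKind.TEXT)
        if value:
            sheet.set_value(row, 2, value, kind=ValueKind.TEXT)
        row += 1
    for i, attr in enumerate(md.attributes, start=1):
        for label, key in _ATTR_ROW_KEYS:
            sheet.set_value(row, 1, f"{label} ({i})", kind=ValueKind.TEXT)
            value = getattr(attr, key)
            if value not in ("", None):
                sheet.set_value(row, 2, str(value), kind=ValueKind.TEXT)
            row += 1
    out.sheets.append(sheet)
    return out


_ATTR_LINE_RE = re.compile(r"^(.*) \((\d+)\)$")


def extract_metadata_sheet(wb: Workbook) -> MetadataRecord:
    """Reconstruct the record from a workbook's "Metadata" sheet."""
    try:
        sheet = wb.sheet(METADATA_SHEET_NAME)
    except KeyError:
        raise SheetReadyError(
            "workbook has no 'Metadata' sheet to extract"
        ) from None
    by_name = {d.name: d for d in _SCHEMA if d.group != "parameter"}
    attr_labels = {label: key for label, key in _ATTR_ROW_KEYS}

    fl = FileMetadata()
    attrs: dict[int, dict[str, str]] = {}
    used = sheet.used_range
    if used is None:
        return MetadataRecord(file_level=fl)
    for row in range(used.top, used.bottom + 1):
        name = sheet.value_at(row, 1)
        if not isinstance(name, str):
            continue
        value = sheet.value_at(row, 2)
        value = "" if value is None else str(value)
        if name in by_name:
            if value:
                fl.set(by_name[name].key, value)
            continue
        m = _ATTR_LINE_RE.match(name)
        if m and m.group(1) in attr_labels:
            attrs.setdefault(int(m.group(2)), {})[
                attr_labels[m.group(1)]
            ] = value

    attributes = []
    for i in sorted(attrs):
        raw = attrs[i]
        attributes.append(
            AttributeMetadata(
                parameter_name=raw.get("parameter_name", ""),
                column_index=int(raw.get("column_index") or 0),
                definition=raw.get("definition", ""),
                units=raw.get("units", ""),
                label=raw.get("label", ""),
                measurement_scale=raw.get("measurement_scale", ""),
            )
        )
    return MetadataRecord(file_level=fl, attributes=attributes)


# ---------------------------------------------------------------------------
# key-value entry files (CLI surface)


def save_meta_file(md: MetadataRecord, path: Union[str, Path]) -> Path:
    """Write a record as a documented ``key: value`` text file."""
    lines = [
        "# sheetready metadata entry file — one 'key: value' per line.",
        "# Keys marked (required) must be filled for a complete record.",
        "# Keywords are separated with ';'.",
        "",
    ]
    for d in _SCHEMA:
        if d.group == "parameter":
            continue
        value = md.file_level.get(d.key)
        if d.key == "keywords":
            value = "; ".join(value)
        suffix = "   # (required)" if d.required and not value else ""
        lines.append(f"{d.key}: {value}{suffix}")
    for i, attr in enumerate(md.attributes, start=1):
        lines.append("")
        for label, key in _ATTR_ROW_KEYS:
            lines.append(f"attribute.{i}.{key}: {getattr(attr, key)}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


_ATTR_KEY_RE = re.compile(r"^attribute\.(\d+)\.([a-z_]+)$")


def load_meta_file(path: Union[str, Path]) -> MetadataRecord:
    """Parse a ``key: value`` metadata entry file."""
    fl = FileMetadata()
    attrs: dict[int, dict[str, str]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if ":" not in stripped:
            raise SheetReadyError(
                f"{path}:{lineno}: expected 'key: value', got {stripped!r}"
            )
        key, _, value = stripped.partition(":")
        key = key.strip()
        value = value.split("#", 1)[0].strip() if "#" in value else value.strip()
        m = _ATTR_KEY_RE.match(key)
        if m:
            attrs.setdefault(int(m.group(1)), {})[m.group(2)] = value
        elif value:
            fl.set(key, value)

    attributes = []
    for i in sorted(attrs):
        raw = attrs[i]
        attributes.append(
            AttributeMetadata(
                parameter_name=raw.get("parameter_name", ""),
                column_index=int(raw.get("column_index") or 0),
                definition=raw.get("definition", ""),
                units=raw.get("units", ""),
                label=raw.get("label", ""),
                measurement_scale=raw.get("measurement_scale", ""),
            )
        )
    return MetadataRecord(file_level=fl, attributes=attributes)
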