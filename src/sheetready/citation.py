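"""Data citations (.ris / .bib / DataCite-style .xml) and ARK identifiers.

Identifiers are minted by a local stateful minter under the ARK test
NAAN 99999 — no network.  The minter state file is plain text
(``naan`` / ``shoulder`` / ``counter`` lines) so it survives between CLI
invocations; counters only move forward, so one state file never hands
out the same identifier twice.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

from .errors import MetadataValidationError, MinterStateError, SheetReadyError
from .metadata import MetadataRecord, validate

__all__ = [
    "Identifier",
    "Citation",
    "MinterState",
    "build_citation",
    "export_citation",
    "mint_ark",
    "mint_ark_file",
    "validate_ark",
    "parse_ark",
    "ark_equal",
    "DEFAULT_NAAN",
    "DEFAULT_SHOULDER",
    "DEFAULT_PUBLISHER",
]

DEFAULT_NAAN = "99999"       # the ARK test namespace
DEFAULT_SHOULDER = "fk4"     # conventional test shoulder
DEFAULT_PUBLISHER = "ONEShare Repository"

_ARK_RE = re.compile(r"^ark:/(\d{5})/([A-Za-z0-9=~*+@_$.\-]+)$")

# Crockford base32: no I, L, O, U — transcription-safe.
_BASE32 = "0123456789abcdefghjkmnpqrstvwxyz"


@dataclass(frozen=True)
class Identifier:
    """A parsed ARK: ``ark:/<naan>/<name>`` (name = shoulder + blade)."""

    naan: str
    name: str
    scheme: str = "ark"

    def __post_init__(self):
        if not validate_ark(self.full):
            raise SheetReadyError(f"not a valid ARK: {self.full!r}")

    @property
    def full(self) -> str:
        return f"ark:/{self.naan}/{self.name}"

    def __str__(self) -> str:
        return self.full


def validate_ark(s: str) -> bool:
    """Pattern check: ``ark:/NNNNN/name`` with no whitespace."""
    return isinstance(s, str) and _ARK_RE.match(s) is not None


def parse_ark(s: str) -> Identifier:
    m = _ARK_RE.match(s) if isinstance(s, str) else None
    if m is None:
        raise SheetReadyError(f"not a valid ARK: {s!r}")
    return Identifier(naan=m.group(1), name=m.group(2))


def ark_equal(a: str, b: str) -> bool:
    """ARK equality ignores hyphens (the transcription rule)."""
    if not (validate_ark(a) and validate_ark(b)):
        return False
    return a.replace("-", "") == b.replace("-", "")


# ---------------------------------------------------------------------------
# minting


@dataclass(frozen=True)
class MinterState:
    naan: str = DEFAULT_NAAN
    shoulder: str = DEFAULT_SHOULDER
    counter: int = 0


def _encode_base32(n: int) -> str:
    if n == 0:
        return _BASE32[0]
    out = ""
    while n > 0:
        n, rem = divmod(n, 32)
        out = _BASE32[rem] + out
    return out


def mint_ark(
    state: MinterState, shoulder: Optional[str] = None
) -> tuple[Identifier, MinterState]:
    """Mint the next identifier; returns (identifier, advanced state)."""
    shoulder = shoulder if shoulder is not None else state.shoulder
    name = f"{shoulder}{_encode_base32(state.counter)}"
    identifier = Identifier(naan=state.naan, name=name)
    return identifier, replace(state, counter=state.counter + 1)


def load_minter_state(path: Union[str, Path]) -> MinterState:
    path = Path(path)
    if not path.exists():
        return MinterState()
    fields = {}
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise MinterStateError(
                f"{path}:{lineno}: expected 'key = value', got {stripped!r}"
            )
        key, _, value = stripped.partition("=")
        fields[key.strip()] = value.strip()
    try:
        naan = fields["naan"]
        shoulder = fields["shoulder"]
        counter = int(fields["counter"])
    except (KeyError, ValueError) as exc:
        raise MinterStateError(
            f"corrupt minter state file {path}: {exc!r}"
        ) from exc
    if not re.match(r"^\d{5}$", naan) or counter < 0:
        raise MinterStateError(
            f"corrupt minter state file {path}: naan={naan!r} "
            f"counter={counter}"
        )
    return MinterState(naan=naan, shoulder=shoulder, counter=counter)


def save_minter_state(state: MinterState, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(
        "# sheetready ARK minter state\n"
        f"naan = {state.naan}\n"
        f"shoulder = {state.shoulder}\n"
        f"counter = {state.counter}\n",
        encoding="utf-8",
    )
    return path


def mint_ark_file(
    path: Union[str, Path], shoulder: Optional[str] = None
) -> Identifier:
    """Mint against an on-disk state file, persisting the new counter."""
    state = load_minter_state(path)
    identifier, new_state = mint_ark(state, shoulder)
    save_minter_state(new_state, path)
    return identifier


# ---------------------------------------------------------------------------
# citations


@dataclass
class Citation:
    creators: list[tuple[str, str]]  # (last, first)
    year: int
    title: str
    publisher: str
    identifier: Optional[Identifier] = None

    @property
    def formatted(self) -> str:
        """DataCite-style: Creator(s) (Year): Title. Publisher. Identifier."""
        names = "; ".join(
            f"{last}, {first}" if first else last
            for last, first in self.creators
        )
        text = f"{names} ({self.year}): {self.title}. {self.publisher}."
        if self.identifier is not None:
            text += f" {self.identifier.full}."
        return text


def build_citation(md: MetadataRecord, year: int) -> Citation:
    """Build a citation from a complete record and write it back into it."""
    findings = validate(md)
    if findings:
        raise MetadataValidationError(findings)
    fl = md.file_level
    creators = [(fl.creator_last_name, fl.creator_first_name)]
    identifier = parse_ark(fl.identifier) if fl.identifier else None
    citation = Citation(
        creators=creators,
        year=year,
        title=fl.dataset_title,
        publisher=fl.publisher or DEFAULT_PUBLISHER,
        identifier=identifier,
    )
    fl.formatted_citation = citation.formatted
    return citation


def _bib_key(citation: Citation) -> str:
    last = citation.creators[0][0] if citation.creators else "dataset"
    stem = re.sub(r"[^A-Za-z0-9]", "", last).lower() or "dataset"
    return f"{stem}{citation.year}"


def export_citation(citation: Citation, fmt: str) -> str:
    """Render a citation as .ris, .bib, or DataCite-style .xml text."""
    if fmt == "ris":
        lines = ["TY  - DATA"]
        for last, first in citation.creators:
            lines.append(f"AU  - {last}, {first}" if first else f"AU  - {last}")
        lines.append(f"PY  - {citation.year}")
        lines.append(f"TI  - {citation.title}")
        lines.append(f"PB  - {citation.publisher}")
        if citation.identifier is not None:
            lines.append(f"ID  - {citation.identifier.full}")
        lines.append("ER  - ")
        return "\n".join(lines) + "\n"

    if fmt == "bib":
        authors = " and ".join(
            f"{last}, {first}" if first else last
            for last, first in citation.creators
        )
        fields = [
            ("author", authors),
            ("year", str(citation.year)),
            ("title", citation.title),
            ("publisher", citation.publisher),
        ]
        if citation.identifier is not None:
            fields.append(("note", citation.identifier.full))
        body = ",\n".join(f"  {k} = {{{v}}}" for k, v in fields)
        return f"@misc{{{_bib_key(citation)},\n{body}\n}}\n"

    if fmt == "xml":
        root = ET.Element("resource")
        ident = ET.SubElement(root, "identifier")
        ident.set("identifierType", "ARK")
        ident.text = citation.identifier.full if citation.identifier else ""
        creators = ET.SubElement(root, "creators")
        for last, first in citation.creators:
            el = ET.SubElement(ET.SubElement(creators, "creator"),
                               "creatorName")
            el.text = f"{last}, {first}" if first else last
        titles = ET.SubElement(root, "titles")
        ET.SubElement(titles, "title").text = citation.title
        ET.SubElement(root, "publisher").text = citation.publisher
        ET.SubElement(root, "publicationYear").text = str(citation.year)
        ET.indent(root)
        return ET.tostring(root, encoding="unicode", xml_declaration=True)

    raise SheetReadyError(
        f"unknown citation format {fmt!r}; expected ris, bib or xml"
    )
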