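"""Deposit readiness, technical metadata, package assembly, and the
repository adapter seam with a filesystem backend.

A package directory holds ``data/`` (exported CSVs), ``eml.xml``,
``citation.{ris,bib,xml}``, ``techmd.json`` and a BagIt-style
``manifest-sha256.txt`` whose checksums cover every payload file.
Readiness gates on the compatibility check having been *run* (not on it
passing), metadata completeness, and a generated citation.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import os
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Protocol, Union

from .checks import CheckReport
from .citation import Citation, Identifier, export_citation, parse_ark
from .errors import DepositError, ManifestError, ReadinessError
from .export import export_csv
from .metadata import MetadataRecord, to_eml
from .model import Workbook

__all__ = [
    "ReadinessResult",
    "TechnicalMetadata",
    "DepositReceipt",
    "assess_readiness",
    "build_package",
    "verify_manifest",
    "deposit",
    "FilesystemAdapter",
]

MANIFEST_NAME = "manifest-sha256.txt"


@dataclass(frozen=True)
class ReadinessResult:
    compatibility_checked: bool
    compatibility_passed: bool
    metadata_complete: bool
    citation_present: bool

    @property
    def ready(self) -> bool:
        return (
            self.compatibility_checked
            and self.metadata_complete
            and self.citation_present
        )

    @property
    def missing_gates(self) -> list[str]:
        gates = []
        if not self.compatibility_checked:
            gates.append("compatibility check has not been run")
        if not self.metadata_complete:
            gates.append("metadata is incomplete")
        if not self.citation_present:
            gates.append("no citation has been generated")
        return gates


def assess_readiness(
    report: Optional[CheckReport],
    md: MetadataRecord,
    citation: Optional[Citation],
) -> ReadinessResult:
    """Pure readiness predicate; a failed check does not block deposit."""
    return ReadinessResult(
        compatibility_checked=report is not None,
        compatibility_passed=report.passed if report is not None else False,
        metadata_complete=md.complete,
        citation_present=citation is not None,
    )


@dataclass(frozen=True)
class FileRecord:
    name: str
    size: int
    sha256: str
    format: str


@dataclass(frozen=True)
class TechnicalMetadata:
    files: tuple[FileRecord, ...]
    total_size: int
    file_count: int
    identifier: str = ""

    def to_dict(self) -> dict:
        return {
            "identifier": self.identifier,
            "file_count": self.file_count,
            "total_size": self.total_size,
            "files": [
                {
                    "name": f.name,
                    "size": f.size,
                    "sha256": f.sha256,
                    "format": f.format,
                }
                for f in self.files
            ],
        }


_MIME = {
    ".csv": "text/csv",
    ".xml": "application/xml",
    ".ris": "application/x-research-info-systems",
    ".bib": "application/x-bibtex",
    ".json": "application/json",
    ".txt": "text/plain",
}


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def build_package(
    wb: Workbook,
    md: MetadataRecord,
    citation: Optional[Citation],
    report: Optional[CheckReport],
    out_dir: Union[str, Path],
) -> tuple[Path, TechnicalMetadata]:
    """Assemble a deposit package; raises unless the dataset is ready."""
    readiness = assess_readiness(report, md, citation)
    if not readiness.ready:
        raise ReadinessError(readiness.missing_gates)
    assert citation is not None

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_dir = out_dir / "data"
    data_dir.mkdir(exist_ok=True)

    export_csv(wb, data_dir)
    (out_dir / "eml.xml").write_text(to_eml(md), encoding="utf-8")
    for fmt in ("ris", "bib", "xml"):
        (out_dir / f"citation.{fmt}").write_text(
            export_citation(citation, fmt), encoding="utf-8"
        )

    payload = sorted(
        p
        for p in out_dir.rglob("*")
        if p.is_file() and p.name not in (MANIFEST_NAME, "techmd.json")
    )
    records = tuple(
        FileRecord(
            name=str(p.relative_to(out_dir)).replace(os.sep, "/"),
            size=p.stat().st_size,
            sha256=_sha256(p),
            format=_MIME.get(p.suffix.lower(), "application/octet-stream"),
        )
        for p in payload
    )
    techmd = TechnicalMetadata(
        files=records,
        total_size=sum(r.size for r in records),
        file_count=len(records),
        identifier=md.file_level.identifier,
    )
    techmd_path = out_dir / "techmd.json"
    techmd_path.write_text(
        json.dumps(techmd.to_dict(), indent=2) + "\n", encoding="utf-8"
    )

    manifest_lines = [f"{r.sha256}  {r.name}" for r in records]
    manifest_lines.append(f"{_sha256(techmd_path)}  techmd.json")
    (out_dir / MANIFEST_NAME).write_text(
        "\n".join(manifest_lines) + "\n", encoding="utf-8"
    )
    return out_dir, techmd


def verify_manifest(package_dir: Union[str, Path]) -> bool:
    """Re-hash every manifest entry; raises :class:`ManifestError` on any
    mismatch or missing file."""
    package_dir = Path(package_dir)
    manifest = package_dir / MANIFEST_NAME
    if not manifest.exists():
        raise ManifestError(f"no {MANIFEST_NAME} in {package_dir}")
    for line in manifest.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        expected, _, rel = line.partition("  ")
        target = package_dir / rel
        if not target.exists():
            raise ManifestError(f"manifest entry missing on disk: {rel}")
        actual = _sha256(target)
        if actual != expected:
            raise ManifestError(
                f"checksum mismatch for {rel}: "
                f"manifest {expected}, actual {actual}"
            )
    return True


# ---------------------------------------------------------------------------
# repository adapter seam


@dataclass(frozen=True)
class DepositReceipt:
    identifier: Identifier
    repository_id: str
    stored_paths: tuple[str, ...]
    deposited_at: str


class RepositoryAdapter(Protocol):
    """Contract for repository backends (Merritt, DataONE, …)."""

    repository_id: str

    def authenticate(self, credentials: Optional[dict] = None) -> None: ...

    def mint(self) -> Identifier: ...

    def store(
        self, package_dir: Path, identifier: Identifier
    ) -> tuple[str, ...]: ...


class FilesystemAdapter:
    """Stores packages under ``<root>/<naan>/<name>/`` and re-verifies the
    manifest after copy; a failed verification removes the partial copy."""

    def __init__(
        self,
        root: Union[str, Path],
        minter_state_path: Optional[Union[str, Path]] = None,
    ):
        self.root = Path(root)
        self.minter_state_path = minter_state_path
        self.repository_id = f"fs:{self.root}"
        self._authenticated = False

    def authenticate(self, credentials: Optional[dict] = None) -> None:
        try:
            self.root.mkdir(parents=True, exist_ok=True)
            probe = self.root / ".sheetready-probe"
            probe.write_text("", encoding="utf-8")
            probe.unlink()
        except OSError as exc:
            raise DepositError(
                f"repository root {self.root} is not writable: {exc}"
            ) from exc
        self._authenticated = True

    def mint(self) -> Identifier:
        from .citation import mint_ark_file

        if self.minter_state_path is None:
            raise DepositError(
                "adapter has no minter state file configured"
            )
        return mint_ark_file(self.minter_state_path)

    def store(
        self, package_dir: Path, identifier: Identifier
    ) -> tuple[str, ...]:
        if not self._authenticated:
            raise DepositError("adapter is not authenticated")
        dest = self.root / identifier.naan / identifier.name
        if dest.exists():
            raise DepositError(f"destination already exists: {dest}")
        try:
            shutil.copytree(package_dir, dest)
            verify_manifest(dest)
        except ManifestError as exc:
            shutil.rmtree(dest, ignore_errors=True)
            raise DepositError(
                f"manifest verification failed after transfer: {exc}"
            ) from exc
        return tuple(
            sorted(
                str(p.relative_to(self.root))
                for p in dest.rglob("*")
                if p.is_file()
            )
        )


def deposit(
    package_dir: Union[str, Path],
    adapter: RepositoryAdapter,
    credentials: Optional[dict] = None,
) -> DepositReceipt:
    """Authenticate, resolve the package identifier, store, and receipt."""
    package_dir = Path(package_dir)
    verify_manifest(package_dir)
    adapter.authenticate(credentials)

    techmd_path = package_dir / "techmd.json"
    identifier: Optional[Identifier] = None
    if techmd_path.exists():
        recorded = json.loads(techmd_path.read_text(encoding="utf-8")).get(
            "identifier", ""
        )
        if recorded:
            identifier = parse_ark(recorded)
    if identifier is None:
        identifier = adapter.mint()

    stored = adapter.store(package_dir, identifier)
    return DepositReceipt(
        identifier=identifier,
        repository_id=adapter.repository_id,
        stored_paths=stored,
        deposited_at=_dt.datetime.now().isoformat(timespec="seconds"),
    )
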