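"""Exception hierarchy for sheetready."""


class SheetReadyError(Exception):
    """Base class for all sheetready errors."""


class FormatError(SheetReadyError):
    """A file could not be read or is not in a supported format."""


class ExportError(SheetReadyError):
    """A workbook could not be exported."""


class MetadataValidationError(SheetReadyError):
    """A metadata record failed validation.

    Carries the individual findings so callers can enumerate them.
    """

    def __init__(self, findings):
        self.findings = list(findings)
        super().__init__(
            "metadata record is not valid: " + "; ".join(self.findings)
        )


class HeaderAbsentError(SheetReadyError):
    """An operation required a header row that was not detected."""


class MinterStateError(SheetReadyError):
    """The identifier minter state file is missing fields or corrupt."""


class ReadinessError(SheetReadyError):
    """A dataset is not ready for packaging; lists the missing gates."""

    def __init__(self, missing_gates):
        self.missing_gates = list(missing_gates)
        super().__init__(
            "dataset not ready for deposit; missing: "
            + ", ".join(self.missing_gates)
        )


class DepositError(SheetReadyError):
    """A deposit failed (authentication or post-transfer verification)."""


class ManifestError(SheetReadyError):
    """A package checksum manifest failed verification."""
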