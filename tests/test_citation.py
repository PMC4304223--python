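import re
import xml.etree.ElementTree as ET

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sheetready.citation import (
    DEFAULT_PUBLISHER,
    Citation,
    Identifier,
    MinterState,
    ark_equal,
    build_citation,
    export_citation,
    load_minter_state,
    mint_ark,
    mint_ark_file,
    parse_ark,
    save_minter_state,
    validate_ark,
)
from sheetready.errors import (
    MetadataValidationError,
    MinterStateError,
    SheetReadyError,
)
from sheetready.metadata import MetadataRecord


class TestArk:
    @pytest.mark.parametrize(
        "value,valid",
        [
            ("ark:/99999/fk4x1", True),
            ("ark:/12345/p9wm13", True),
            ("doi:10.1/abc", False),
            ("ark:/999/fk4", False),       # naan must be 5 digits
            ("ark:/99999/fk4 x1", False),  # no whitespace
            ("ark:/99999/", False),
        ],
    )
    def test_validate(self, value, valid):
        assert validate_ark(value) is valid

    def test_parse(self):
        ident = parse_ark("ark:/99999/fk4x1")
        assert (ident.naan, ident.name) == ("99999", "fk4x1")
        assert ident.full == "ark:/99999/fk4x1"

    def test_parse_rejects(self):
        with pytest.raises(SheetReadyError):
            parse_ark("not-an-ark")

    def test_hyphen_insensitive_equality(self):
        assert ark_equal("ark:/99999/fk4-x1", "ark:/99999/fk4x1")
        assert not ark_equal("ark:/99999/fk4x1", "ark:/99999/fk4x2")

    def test_identifier_invariant(self):
        with pytest.raises(SheetReadyError):
            Identifier(naan="99", name="x")


class TestMinter:
    def test_shoulder_prefix(self):
        ident, _ = mint_ark(MinterState(), "fk4")
        assert ident.name.startswith("fk4")

    def test_two_mints_distinct(self):
        ident1, state = mint_ark(MinterState())
        ident2, _ = mint_ark(state)
        assert ident1.full != ident2.full

    def test_minted_validates(self):
        ident, _ = mint_ark(MinterState())
        assert validate_ark(ident.full)

    @settings(max_examples=20)
    @given(st.integers(min_value=0, max_value=10**9))
    def test_counter_injective(self, counter):
        a, _ = mint_ark(MinterState(counter=counter))
        b, _ = mint_ark(MinterState(counter=counter + 1))
        assert a.full != b.full

    def test_state_file_roundtrip(self, tmp_path):
        path = tmp_path / "state.txt"
        save_minter_state(MinterState(counter=41), path)
        assert load_minter_state(path) == MinterState(counter=41)

    def test_file_minting_persists(self, tmp_path):
        path = tmp_path / "state.txt"
        ids = [mint_ark_file(path).full for _ in range(10)]
        assert len(set(ids)) == 10
        assert load_minter_state(path).counter == 10

    def test_corrupt_state_rejected(self, tmp_path):
        path = tmp_path / "state.txt"
        path.write_text("naan = 99999\nshoulder = fk4\ncounter = lots\n")
        with pytest.raises(MinterStateError, match="corrupt"):
            mint_ark_file(path)

    def test_garbled_state_rejected(self, tmp_path):
        path = tmp_path / "state.txt"
        path.write_text("??\n")
        with pytest.raises(MinterStateError):
            mint_ark_file(path)


class TestBuildCitation:
    def test_formatted_without_identifier(self, minimal_record):
        citation = build_citation(minimal_record, 2012)
        assert citation.formatted == (
            f"Doe, Avery (2012): Creek survey. {DEFAULT_PUBLISHER}."
        )
        assert citation.formatted.endswith(f"{DEFAULT_PUBLISHER}.")

    def test_identifier_included(self, minimal_record):
        minimal_record.file_level.identifier = "ark:/99999/fk40"
        citation = build_citation(minimal_record, 2012)
        assert "ark:/" in citation.formatted

    def test_written_back_to_metadata(self, minimal_record):
        citation = build_citation(minimal_record, 2012)
        assert minimal_record.file_level.formatted_citation == (
            citation.formatted
        )

    def test_incomplete_rejected(self):
        with pytest.raises(MetadataValidationError):
            build_citation(MetadataRecord(), 2012)

    def test_two_creators_joined(self):
        citation = Citation(
            creators=[("Doe", "Avery"), ("Roe", "Jay")],
            year=2012, title="T", publisher="P",
        )
        assert "Doe, Avery; Roe, Jay" in citation.formatted


class TestExportCitation:
    @pytest.fixture
    def citation(self, minimal_record):
        minimal_record.file_level.identifier = "ark:/99999/fk40"
        return build_citation(minimal_record, 2012)

    def test_ris_structure(self, citation):
        # RIS oracle: type tag first, tag-value lines, ER terminator
        ris = export_citation(citation, "ris")
        lines = ris.strip().splitlines()
        assert lines[0] == "TY  - DATA"
        assert lines[-1].startswith("ER  -")
        assert all(re.match(r"^[A-Z][A-Z0-9]  -( |$)", l) for l in lines)
        assert "AU  - Doe, Avery" in lines
        assert "PY  - 2012" in lines

    def test_bib_parses_as_single_misc(self, citation):
        # minimal BibTeX grammar oracle
        bib = export_citation(citation, "bib")
        m = re.match(
            r"@misc\{(?P<key>[a-z0-9]+),\n(?P<body>(  \w+ = \{[^{}]*\},?\n)+)\}\n$",
            bib,
        )
        assert m is not None
        assert m.group("key") == "doe2012"
        assert bib.count("@") == 1

    def test_xml_roundtrip_title(self, citation):
        root = ET.fromstring(export_citation(citation, "xml"))
        assert root.find("titles/title").text == "Creek survey"
        assert root.find("identifier").get("identifierType") == "ARK"

    def test_cross_format_consistency(self, citation):
        ris = export_citation(citation, "ris")
        bib = export_citation(citation, "bib")
        xml = export_citation(citation, "xml")
        for fragment in ("Doe", "2012", "Creek survey", "ark:/99999/fk40"):
            assert fragment in ris
            assert fragment in bib
            assert fragment in xml

    def test_unknown_format(self, citation):
        with pytest.raises(SheetReadyError, match="format"):
            export_citation(citation, "endnote")
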