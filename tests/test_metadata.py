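import xml.etree.ElementTree as ET

import pytest

from conftest import make_minimal_record
from sheetready.errors import HeaderAbsentError, MetadataValidationError
from sheetready.fixtures import generate_fixture
from sheetready.metadata import (
    AttributeMetadata,
    MetadataRecord,
    attributes_from_header,
    embed_metadata_sheet,
    extract_metadata_sheet,
    from_eml,
    load_meta_file,
    prepopulate,
    required_elements,
    save_meta_file,
    schema_elements,
    to_eml,
    validate,
)
from sheetready.model import Sheet, Workbook
from sheetready.regions import detect_regions


class TestSchema:
    def test_47_elements(self):
        assert len(schema_elements()) == 47

    def test_7_required(self):
        required = required_elements()
        assert len(required) == 7
        assert {d.name for d in required} == {
            "Today's date",
            "Title of dataset",
            "Abstract",
            "Keyword(s)",
            "Creator: First name",
            "Creator: Last name",
            "Creator: Email",
        }

    def test_groups(self):
        groups = [d.group for d in schema_elements()]
        assert groups.count("basic") == 7
        assert groups.count("personnel") == 20
        assert groups.count("dataset") == 15
        assert groups.count("parameter") == 5

    def test_keys_unique_and_ordered(self):
        keys = [d.key for d in schema_elements()]
        assert len(set(keys)) == len(keys)
        assert keys[0] == "today_date"


class TestCompleteness:
    def test_minimal_is_complete(self, minimal_record):
        assert minimal_record.complete
        assert validate(minimal_record) == []

    @pytest.mark.parametrize(
        "key", [d.key for d in required_elements()]
    )
    def test_any_six_not_complete(self, key):
        rec = make_minimal_record()
        rec.file_level.set(key, [] if key == "keywords" else "")
        assert not rec.complete
        findings = validate(rec)
        assert len(findings) == 1

    def test_missing_abstract_named(self):
        rec = make_minimal_record()
        rec.file_level.abstract = ""
        assert validate(rec) == ["Required element missing: Abstract"]

    def test_bounding_box_invariant(self, minimal_record):
        fl = minimal_record.file_level
        fl.south_bounding, fl.north_bounding = "50", "40"
        findings = validate(minimal_record)
        assert any("South bounding" in f and "North" in f for f in findings)

    def test_coordinate_ranges(self, minimal_record):
        minimal_record.file_level.west_bounding = "-200"
        assert any("out of range" in f for f in validate(minimal_record))

    def test_bad_date(self, minimal_record):
        minimal_record.file_level.temporal_begin = "Aug 1 2011"
        assert any("ISO 8601" in f for f in validate(minimal_record))

    def test_bad_email(self, minimal_record):
        minimal_record.file_level.creator_email = "nobody"
        assert any("address" in f for f in validate(minimal_record))


class TestPrepopulate:
    def test_author_split_on_last_whitespace(self):
        wb = Workbook(doc_properties={"author": "Carly Strasser"})
        md = prepopulate(wb)
        assert md.creator_first_name == "Carly"
        assert md.creator_last_name == "Strasser"

    def test_multiword_author(self):
        wb = Workbook(doc_properties={"author": "Mary Jane van Dyke"})
        md = prepopulate(wb)
        assert md.creator_first_name == "Mary Jane van"
        assert md.creator_last_name == "Dyke"

    def test_missing_author(self):
        md = prepopulate(Workbook())
        assert md.creator_first_name == "" and md.creator_last_name == ""

    def test_title_fallback_to_stem(self):
        wb = Workbook(source_path="/tmp/creek_data.xlsx")
        assert prepopulate(wb).dataset_title == "creek_data"

    def test_title_preferred(self):
        wb = Workbook(
            doc_properties={"title": "My dataset"}, source_path="x.xlsx"
        )
        assert prepopulate(wb).dataset_title == "My dataset"

    def test_today_filled(self):
        assert prepopulate(Workbook()).today_date != ""


class TestAttributesFromHeader:
    def test_stub_per_column(self):
        wb, _ = generate_fixture([], seed=0)
        sheet = wb.sheets[0]
        region = detect_regions(sheet)[0]
        stubs = attributes_from_header(region, sheet)
        assert [s.parameter_name for s in stubs] == [
            "site", "reading", "sampled",
        ]
        assert [s.column_index for s in stubs] == [1, 2, 3]
        assert all(s.definition == "" and s.units == "" for s in stubs)

    def test_single_column(self):
        sheet = Sheet(name="s")
        sheet.set_value(1, 1, "only")
        sheet.set_value(2, 1, 5)
        region = detect_regions(sheet)[0]
        assert len(attributes_from_header(region, sheet)) == 1

    def test_header_absent_errors(self):
        sheet = Sheet(name="s")
        sheet.set_value(1, 1, 1)
        sheet.set_value(2, 1, 2)
        region = detect_regions(sheet)[0]
        with pytest.raises(HeaderAbsentError, match="unique parameter names"):
            attributes_from_header(region, sheet)


class TestEml:
    def test_minimal_roundtrip(self, minimal_record):
        document = to_eml(minimal_record)
        root = ET.fromstring(document)  # well-formed
        assert root.tag.endswith("eml")
        back = from_eml(document)
        assert back.file_level.dataset_title == "Creek survey"
        assert back.file_level.keywords == ["water", "creek"]

    def test_full_record_roundtrip(self, full_record):
        back = from_eml(to_eml(full_record))
        assert back.file_level == full_record.file_level
        assert back.attributes == full_record.attributes

    def test_attribute_list_entries(self, minimal_record):
        minimal_record.attributes = [
            AttributeMetadata(f"p{i}", i) for i in (1, 2, 3)
        ]
        root = ET.fromstring(to_eml(minimal_record))
        attrs = root.findall(".//attributeList/attribute")
        assert len(attrs) == 3

    def test_incomplete_record_rejected(self):
        with pytest.raises(MetadataValidationError) as err:
            to_eml(MetadataRecord())
        assert len(err.value.findings) == 7


class TestMetadataSheet:
    def test_embed_extract_roundtrip(self, full_record):
        wb, _ = generate_fixture([], seed=0)
        embedded = embed_metadata_sheet(wb, full_record)
        back = extract_metadata_sheet(embedded)
        assert back.file_level == full_record.file_level
        assert back.attributes == full_record.attributes

    def test_existing_sheet_replaced(self, minimal_record, full_record):
        wb, _ = generate_fixture([], seed=0)
        embedded = embed_metadata_sheet(
            embed_metadata_sheet(wb, minimal_record), full_record
        )
        assert embedded.sheet_names.count("Metadata") == 1
        assert (
            extract_metadata_sheet(embedded).file_level
            == full_record.file_level
        )

    def test_data_sheets_untouched(self, minimal_record):
        wb, _ = generate_fixture([], seed=0)
        embedded = embed_metadata_sheet(wb, minimal_record)
        original = {
            k: (c.raw_value, c.value_kind)
            for k, c in wb.sheets[0].cells.items()
        }
        after = {
            k: (c.raw_value, c.value_kind)
            for k, c in embedded.sheet("data").cells.items()
        }
        assert original == after

    def test_eml_consistent_through_embedding(self, full_record):
        # embed -> extract -> to_eml equals to_eml directly
        wb, _ = generate_fixture([], seed=0)
        direct = to_eml(full_record)
        extracted = extract_metadata_sheet(
            embed_metadata_sheet(wb, full_record)
        )
        assert to_eml(extracted) == direct


class TestMetaFile:
    def test_roundtrip(self, tmp_path, full_record):
        path = save_meta_file(full_record, tmp_path / "meta.txt")
        back = load_meta_file(path)
        assert back.file_level == full_record.file_level
        assert back.attributes == full_record.attributes

    def test_bad_line_rejected(self, tmp_path):
        path = tmp_path / "meta.txt"
        path.write_text("just some words\n")
        with pytest.raises(Exception, match="key: value"):
            load_meta_file(path)
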