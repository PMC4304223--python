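import pytest

from sheetready.metadata import AttributeMetadata, MetadataRecord


def make_minimal_record() -> MetadataRecord:
    """A record with exactly the 7 required elements filled."""
    rec = MetadataRecord()
    fl = rec.file_level
    fl.today_date = "2012-10-01"
    fl.dataset_title = "Creek survey"
    fl.abstract = "Water chemistry measurements."
    fl.keywords = ["water", "creek"]
    fl.creator_first_name = "Avery"
    fl.creator_last_name = "Doe"
    fl.creator_email = "avery@example.org"
    return rec


def make_full_record() -> MetadataRecord:
    """A record with every one of the 42 file-level elements populated,
    plus two column attributes."""
    rec = make_minimal_record()
    fl = rec.file_level
    fl.keyword_thesaurus = "LTER controlled vocabulary"
    fl.identifier = "ark:/99999/fk40"
    fl.formatted_citation = "Doe, Avery (2012): Creek survey. ONEShare."
    fl.creator_organization = "UC"
    fl.creator_address = "1 Shields Ave"
    fl.creator_city = "Oakland"
    fl.creator_state = "CA"
    fl.creator_postal_code = "94612"
    fl.creator_country = "USA"
    fl.creator_phone = "555-0100"
    for key in (
        "first_name", "last_name", "organization", "address", "city",
        "state", "postal_code", "country", "phone",
    ):
        fl.set(f"contact_{key}", f"contact {key.replace('_', ' ')}")
    fl.contact_email = "contact@example.org"
    fl.temporal_begin = "2011-08-01"
    fl.temporal_end = "2011-08-08"
    fl.geographic_description = "Lower creek reach"
    fl.west_bounding = "-122.3"
    fl.east_bounding = "-122.1"
    fl.north_bounding = "37.9"
    fl.south_bounding = "37.7"
    fl.intellectual_rights = "CC0"
    fl.project_title = "Creek monitoring"
    fl.project_description = "Long-term creek monitoring."
    fl.project_personnel = "Doe"
    fl.project_personnel_role = "principal investigator"
    fl.publisher = "ONEShare"
    fl.data_table_name = "readings"
    fl.data_table_description = "One row per site visit."
    rec.attributes = [
        AttributeMetadata(
            "site", 1, definition="site identifier", units="none",
            label="Site", measurement_scale="nominal",
        ),
        AttributeMetadata("reading", 2, definition="value", units="mg/L"),
    ]
    return rec


@pytest.fixture
def minimal_record():
    return make_minimal_record()


@pytest.fixture
def full_record():
    return make_full_record()
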