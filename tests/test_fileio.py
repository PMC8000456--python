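"""Serialization round trips, parse-defect classification, source dispatch."""

import json

import pytest

from mwkit import fileio, model
from mwkit.errors import ParseError
from mwkit.fixtures import PARSE_DEFECT_CLASSES, FixtureSpec, generate_entry, inject_defect
from mwkit.mwrest import MockTransport
from tests.conftest import make_entry


@pytest.mark.parametrize("analysis_type,extended", [
    ("MS", False),
    ("MS", True),
    ("NMR-targeted", False),
    ("NMR-binned", False),
])
def test_text_round_trip_identity(analysis_type, extended):
    entry, _ = make_entry(seed=21, analysis_type=analysis_type, extended=extended)
    text = fileio.write_mwtab(entry)
    reparsed = fileio.parse_mwtab(text)
    assert model.equal_entries(entry, reparsed)
    assert fileio.write_mwtab(reparsed) == text


@pytest.mark.parametrize("analysis_type", ["MS", "NMR-targeted", "NMR-binned"])
def test_json_round_trip_identity(analysis_type):
    entry, _ = make_entry(seed=22, analysis_type=analysis_type)
    payload = fileio.write_json(entry)
    reparsed = fileio.parse_json(payload)
    assert model.equal_entries(entry, reparsed)
    assert fileio.write_json(reparsed) == payload


def test_cross_serialization_equivalence(ms_entry_extended):
    entry, _ = ms_entry_extended
    from_text = fileio.parse_mwtab(fileio.write_mwtab(entry))
    from_json = fileio.parse_json(fileio.write_json(entry))
    assert model.equal_entries(from_text, from_json,
                               model.NormalizationPolicy.NORMALIZED)


def test_parsed_sections_preserve_file_order(ms_entry):
    entry, _ = ms_entry
    reparsed = fileio.parse_mwtab(fileio.write_mwtab(entry))
    assert list(reparsed.sections) == list(entry.sections)


def test_extended_block_nests_inside_metabolites_section(ms_entry_extended):
    entry, _ = ms_entry_extended
    text = fileio.write_mwtab(entry)
    assert "EXTENDED_MS_METABOLITE_DATA_START" in text
    # nested: no '#'-header of its own, it lives inside #METABOLITES
    assert "#EXTENDED_MS_METABOLITE_DATA" not in text
    block = fileio.parse_mwtab(text).sections["EXTENDED_MS_METABOLITE_DATA"]
    assert block.headings[0] == "sample_id"
    assert all(row.values["sample_id"] for row in block.rows)


def test_minimal_entry_writes_banner_and_terminator_only():
    entry = model.MWTabEntry(header_ids={"ANALYSIS_ID": "AN000001"})
    text = fileio.write_mwtab(entry)
    assert text == "#METABOLOMICS WORKBENCH ANALYSIS_ID:AN000001\n#END\n"


def test_empty_body_rejected_with_distinct_code():
    for body in ("", "   \n\n"):
        with pytest.raises(ParseError) as err:
            fileio.parse_mwtab(body)
        assert err.value.code == "empty_file"
        with pytest.raises(ParseError) as err:
            fileio.parse_json(body)
        assert err.value.code == "empty_file"


@pytest.mark.parametrize("defect_class", PARSE_DEFECT_CLASSES)
def test_injected_parse_defects_raise_matching_code(defect_class):
    entry, _ = make_entry(seed=31)
    text = fileio.write_mwtab(entry)
    mutated, record = inject_defect(text, defect_class, seed=31)
    with pytest.raises(ParseError) as err:
        fileio.parse_mwtab(mutated)
    assert err.value.code == defect_class
    assert err.value.line_number == record.line_number


def test_duplicate_item_error_names_line():
    entry, _ = make_entry(seed=32)
    text = fileio.write_mwtab(entry)
    mutated, record = inject_defect(text, "duplicate_item", seed=1)
    with pytest.raises(ParseError) as err:
        fileio.parse_mwtab(mutated)
    assert "INSTITUTE" in str(err.value)
    assert err.value.line_number == record.line_number


def test_json_syntax_error():
    with pytest.raises(ParseError) as err:
        fileio.parse_json("{")
    assert err.value.code == "json_syntax"


def test_json_missing_banner():
    with pytest.raises(ParseError) as err:
        fileio.parse_json(json.dumps({"PROJECT": {}}))
    assert err.value.code == "missing_banner"


def test_json_wrong_structure_names_section(ms_entry):
    entry, _ = ms_entry
    doc = json.loads(fileio.write_json(entry))
    doc["CHROMATOGRAPHY"] = ["not", "a", "mapping"]
    with pytest.raises(ParseError) as err:
        fileio.parse_json(json.dumps(doc))
    assert err.value.code == "wrong_structure"
    assert "CHROMATOGRAPHY" in str(err.value)


def test_format_detection():
    assert fileio.detect_format("#METABOLOMICS WORKBENCH ...") == "mwtab_text"
    assert fileio.detect_format('  {"METABOLOMICS WORKBENCH": {}}') == "json"
    with pytest.raises(ParseError):
        fileio.detect_format("neither format")


def test_read_entries_from_directory_in_name_order(tmp_path):
    ids = []
    for i in range(3):
        entry, manifest = make_entry(seed=40 + i)
        (tmp_path / f"{manifest['analysis_id']}.txt").write_text(
            fileio.write_mwtab(entry), encoding="utf-8")
        ids.append(manifest["analysis_id"])
    entries = list(fileio.read_entries([tmp_path]))
    assert [e.analysis_id for e in entries] == sorted(ids)


def test_read_entries_yields_error_records_not_skips(tmp_path):
    (tmp_path / "broken.txt").write_text("no banner here\tx", encoding="utf-8")
    results = list(fileio.read_entries([tmp_path / "broken.txt"]))
    assert len(results) == 1
    assert isinstance(results[0], fileio.EntryError)


def test_read_entries_from_url_via_mock_transport(ms_entry):
    entry, _ = ms_entry
    url = "https://example.org/rest/study/analysis_id/AN000001/mwtab/txt"
    transport = MockTransport({url: fileio.write_mwtab(entry)})
    (result,) = list(fileio.read_entries([url], transport=transport))
    assert model.equal_entries(result, entry, model.NormalizationPolicy.STRIPPED)


def test_read_raw_returns_body_verbatim():
    transport = MockTransport({"https://example.org/x.csv": "a,b\n1,2"})
    raw = fileio.read_raw("https://example.org/x.csv", transport)
    assert raw.text == "a,b\n1,2"
    assert raw.source.endswith("x.csv")


def test_read_raw_404_raises():
    from mwkit.errors import RetrievalError

    with pytest.raises(RetrievalError):
        fileio.read_raw("https://example.org/missing", MockTransport())
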