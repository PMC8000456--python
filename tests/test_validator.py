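"""Validator behavior: the five checkers and their finding codes."""

import copy

import pytest

from mwkit import fileio
from mwkit.fixtures import VALIDATION_DEFECT_CLASSES, inject_defect
from mwkit.model import Row
from mwkit.validator import (
    SchemaSpec,
    check_data_presence,
    check_metabolite_consistency,
    check_numeric_data,
    check_sample_consistency,
    is_numeric,
    validate_entry,
)
from tests.conftest import make_entry


@pytest.mark.parametrize("analysis_type,extended,results_only", [
    ("MS", False, False),
    ("MS", True, False),
    ("MS", False, True),
    ("NMR-targeted", False, False),
    ("NMR-binned", False, False),
])
def test_clean_entries_produce_empty_reports(analysis_type, extended, results_only):
    entry, _ = make_entry(seed=50, analysis_type=analysis_type,
                          extended=extended, results_file_only=results_only)
    report = validate_entry(entry)
    assert not report, report.codes()


@pytest.mark.parametrize("defect_class", VALIDATION_DEFECT_CLASSES)
def test_injected_defect_reported_exactly_once_at_locus(defect_class):
    extended = defect_class == "sample_id_inconsistent_extended"
    entry, _ = make_entry(seed=51, extended=extended)
    mutated, record = inject_defect(entry, defect_class, seed=51)
    report = validate_entry(mutated)
    assert report.codes() == [defect_class]
    assert report.findings[0].locus == record.locus


def test_data_block_samples_may_be_subset_of_declared(ms_entry):
    entry, _ = ms_entry
    entry = copy.deepcopy(entry)
    block = entry.sections["MS_METABOLITE_DATA"]
    dropped = block.sample_ids.pop()
    for row in block.rows:
        del row.values[dropped]
    assert check_sample_consistency(entry) == []


def test_undeclared_data_sample_is_named(ms_entry):
    entry, _ = ms_entry
    entry = copy.deepcopy(entry)
    block = entry.sections["MS_METABOLITE_DATA"]
    block.sample_ids.append("S_GHOST")
    for row in block.rows:
        row.values["S_GHOST"] = "1.0"
    findings = check_sample_consistency(entry)
    assert [f.code for f in findings] == ["sample_id_inconsistent"]
    assert findings[0].locus == "S_GHOST"


def test_blank_sample_id_flagged(ms_entry):
    entry, _ = ms_entry
    entry = copy.deepcopy(entry)
    ssf = entry.sections["SUBJECT_SAMPLE_FACTORS"]
    victim = ssf[-1].sample_id
    ssf[-1].sample_id = ""
    codes = [f.code for f in check_sample_consistency(entry)]
    # the blank itself, plus the now-undeclared data-block sample
    assert "ssf_null_field" in codes
    assert "sample_id_inconsistent" in codes
    assert victim in [f.locus for f in check_sample_consistency(entry)]


def test_metabolite_sets_must_coincide(ms_entry):
    entry, _ = ms_entry
    entry = copy.deepcopy(entry)
    meta = entry.sections["METABOLITES"]
    removed = meta.rows.pop()
    findings = check_metabolite_consistency(entry)
    assert [f.code for f in findings] == ["metabolite_name_inconsistent"]
    assert findings[0].locus == removed.label


def test_blank_metabolite_name_flagged(ms_entry):
    entry, _ = ms_entry
    entry = copy.deepcopy(entry)
    block = entry.sections["MS_METABOLITE_DATA"]
    meta = entry.sections["METABOLITES"]
    block.rows[0].label = ""
    meta.rows[0].label = ""
    codes = [f.code for f in check_metabolite_consistency(entry)]
    assert codes.count("metabolite_name_blank") == 2


@pytest.mark.parametrize("value,numeric", [
    ("1.5e3", True),
    ("0", True),
    ("-0.2", True),
    ("+12.", True),
    (".5", True),
    ("", True),            # allowed missing token
    ("N/A*", False),
    ("1,5", False),
    ("12 000", False),
    ("NaN", False),
])
def test_numeric_cell_grammar(value, numeric):
    assert is_numeric(value) is numeric


def test_non_numeric_cell_located_by_metabolite_and_sample(ms_entry):
    entry, _ = ms_entry
    entry = copy.deepcopy(entry)
    block = entry.sections["MS_METABOLITE_DATA"]
    row = block.rows[2]
    sample = block.sample_ids[1]
    row.values[sample] = "N/A*"
    findings = check_numeric_data(entry)
    assert [f.code for f in findings] == ["non_numeric_data"]
    assert findings[0].locus == f"{row.label}/{sample}"


def test_data_presence_rule_for_ms():
    entry, _ = make_entry(seed=52, results_file_only=True)
    assert check_data_presence(entry) == []
    stripped = copy.deepcopy(entry)
    stripped.sections["MS"].items.pop("MS_RESULTS_FILE")
    findings = check_data_presence(stripped)
    assert [f.code for f in findings] == ["missing_data_no_results_file"]


def test_data_presence_rule_for_nmr_is_unconditional():
    entry, _ = make_entry(seed=53, analysis_type="NMR-targeted")
    entry = copy.deepcopy(entry)
    for name in ("NMR_METABOLITE_DATA", "METABOLITES"):
        entry.sections.pop(name, None)
    findings = check_data_presence(entry)
    assert [f.code for f in findings] == ["missing_data_no_results_file"]


def test_null_required_item_yields_two_distinct_findings(ms_entry):
    entry, _ = ms_entry
    entry = copy.deepcopy(entry)
    entry.sections["COLLECTION"].items["COLLECTION_SUMMARY"] = "N/A"
    report = validate_entry(entry)
    assert sorted(report.codes()) == ["null_item_value", "schema_missing_item"]
    # a merely *missing* required item is only the schema finding
    del entry.sections["COLLECTION"].items["COLLECTION_SUMMARY"]
    report = validate_entry(entry)
    assert sorted(report.codes()) == ["schema_missing_item"]


def test_schema_requires_chromatography_only_for_ms():
    ms, _ = make_entry(seed=54, analysis_type="MS")
    nmr, _ = make_entry(seed=54, analysis_type="NMR-targeted")
    assert "CHROMATOGRAPHY" in SchemaSpec.default().sections_for("MS")
    assert "CHROMATOGRAPHY" not in SchemaSpec.default().sections_for("NMR")
    assert not validate_entry(nmr)
    broken = copy.deepcopy(ms)
    del broken.sections["CHROMATOGRAPHY"]
    assert "schema_missing_section" in validate_entry(broken).codes()


def test_monotonicity_adding_defect_preserves_existing_findings(ms_entry):
    entry, _ = ms_entry
    one, _ = inject_defect(copy.deepcopy(entry), "null_item_value", seed=1)
    first = set(validate_entry(one).codes())
    two, _ = inject_defect(one, "schema_missing_item", seed=2)
    second = validate_entry(two).codes()
    assert first <= set(second)


def test_reports_survive_serialization_round_trip(ms_entry):
    entry, _ = ms_entry
    assert not validate_entry(entry)
    reparsed = fileio.parse_mwtab(fileio.write_mwtab(entry))
    assert not validate_entry(reparsed)
    reparsed_json = fileio.parse_json(fileio.write_json(entry))
    assert not validate_entry(reparsed_json)


def test_report_exports(ms_entry):
    entry, _ = ms_entry
    mutated, _ = inject_defect(copy.deepcopy(entry), "null_item_value", seed=3)
    report = validate_entry(mutated, source="AN000001")
    assert "null_item_value" in report.to_json()
    assert report.to_tsv().startswith("code\tsection\tlocus")


def test_report_is_deterministic(ms_entry):
    entry, _ = ms_entry
    mutated, _ = inject_defect(copy.deepcopy(entry), "sample_id_inconsistent", seed=4)
    assert validate_entry(mutated).findings == validate_entry(mutated).findings
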