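"""Fixture generator: determinism, self-validation, corpus allocation."""

import json

import pytest

from mwkit import fileio, model, validator
from mwkit.crossformat import compare_entries
from mwkit.errors import InjectionError
from mwkit.fixtures import (
    FixtureSpec,
    generate_corpus,
    generate_entry,
    inject_defect,
    subseed,
)


def test_same_spec_and_seed_are_byte_identical():
    a, _ = generate_entry(FixtureSpec(seed=9, extended=True))
    b, _ = generate_entry(FixtureSpec(seed=9, extended=True))
    assert fileio.write_mwtab(a) == fileio.write_mwtab(b)
    assert fileio.write_json(a) == fileio.write_json(b)


def test_different_seeds_differ():
    a, _ = generate_entry(FixtureSpec(seed=1))
    b, _ = generate_entry(FixtureSpec(seed=2))
    assert fileio.write_mwtab(a) != fileio.write_mwtab(b)


def test_subseed_is_stable_and_bounded():
    assert subseed(1, 2) == subseed(1, 2)
    assert subseed(1, 2) != subseed(1, 3)
    assert 0 <= subseed(12345, "ssf_malformed") < 2**31


def test_generated_entries_self_validate():
    for seed in range(4):
        entry, _ = generate_entry(FixtureSpec(seed=seed))
        assert not validator.validate_entry(entry)


def test_manifest_matches_entry_content():
    entry, manifest = generate_entry(FixtureSpec(seed=30, n_samples=4,
                                                 n_metabolites=3))
    block = entry.sections["MS_METABOLITE_DATA"]
    assert block.sample_ids == manifest["sample_ids"]
    assert len(block.sample_ids) == 4
    assert block.metabolite_names() == manifest["metabolites"]
    assert len(block.rows) == 3
    assert entry.analysis_id == manifest["analysis_id"]


def test_extended_flag_plants_per_sample_rows():
    entry, manifest = generate_entry(FixtureSpec(seed=31, extended=True))
    block = entry.sections["EXTENDED_MS_METABOLITE_DATA"]
    keys = {(r.label, r.values["sample_id"]) for r in block.rows}
    assert keys == {(m, s) for m in manifest["metabolites"]
                    for s in manifest["sample_ids"]}


def test_results_file_only_entries_are_valid_without_data():
    entry, manifest = generate_entry(FixtureSpec(seed=32, results_file_only=True))
    assert "MS_METABOLITE_DATA" not in entry.sections
    assert "MS_RESULTS_FILE" in entry.sections["MS"].items
    assert not validator.validate_entry(entry)
    assert manifest["metabolites"] == []


def test_inconsistent_spec_rejected():
    with pytest.raises(ValueError):
        FixtureSpec(n_samples=0)
    with pytest.raises(ValueError):
        FixtureSpec(analysis_type="GC")
    with pytest.raises(ValueError):
        FixtureSpec(results_file_only=True, analysis_type="NMR-targeted")


def test_inapplicable_injection_raises():
    entry, _ = generate_entry(FixtureSpec(seed=33))
    with pytest.raises(InjectionError):
        inject_defect(entry, "ssf_malformed", seed=1)       # text-only class
    with pytest.raises(InjectionError):
        inject_defect("some text", "null_item_value", seed=1)
    with pytest.raises(InjectionError):
        inject_defect(entry, "sample_id_inconsistent_extended", seed=1)
    with pytest.raises(InjectionError):
        inject_defect(entry, "not_a_class", seed=1)


def test_blank_body_injection():
    entry, _ = generate_entry(FixtureSpec(seed=34))
    mutated, record = inject_defect(fileio.write_mwtab(entry), "blank_body", 1)
    assert mutated == ""
    assert record.defect_class == "blank_body"


def test_clean_pairs_pass_full_pipeline():
    for seed in range(3):
        entry, _ = generate_entry(FixtureSpec(seed=seed, extended=seed == 1))
        text_entry = fileio.parse_mwtab(fileio.write_mwtab(entry))
        json_entry = fileio.parse_json(fileio.write_json(entry))
        assert not validator.validate_entry(text_entry)
        assert compare_entries(text_entry, json_entry) == []


def test_corpus_allocation_and_determinism(tmp_path):
    mix = {"ssf_malformed": 0.2}
    manifest = generate_corpus(50, mix, seed=8, destination=tmp_path / "a")
    defective = [f for f in manifest["files"] if f["defect"]]
    assert len(defective) == 10
    assert all(f["defect"]["class"] == "ssf_malformed" for f in defective)
    again = generate_corpus(50, mix, seed=8, destination=tmp_path / "b")
    for f in manifest["files"]:
        name = f["analysis_id"]
        assert (tmp_path / "a" / f"{name}.txt").read_bytes() == \
            (tmp_path / "b" / f"{name}.txt").read_bytes()
        assert (tmp_path / "a" / f"{name}.json").read_bytes() == \
            (tmp_path / "b" / f"{name}.json").read_bytes()
    assert manifest == again


def test_corpus_with_no_defects_is_all_clean(tmp_path):
    manifest = generate_corpus(5, seed=9, destination=tmp_path)
    assert all(f["defect"] is None for f in manifest["files"])
    for f in manifest["files"]:
        text = (tmp_path / f"{f['analysis_id']}.txt").read_text(encoding="utf-8")
        entry = fileio.parse_mwtab(text)
        assert not validator.validate_entry(entry)


def test_corpus_fraction_overflow_rejected():
    with pytest.raises(ValueError):
        generate_corpus(10, {"ssf_malformed": 0.7, "version_line": 0.5}, seed=1)


def test_corpus_manifest_written(tmp_path):
    generate_corpus(3, seed=10, destination=tmp_path)
    saved = json.loads((tmp_path / "manifest.json").read_text())
    assert saved["n"] == 3
    assert len(saved["files"]) == 3


def test_injected_defects_detected_by_targeted_module_only():
    """Each defect class is caught by exactly its target checker, with no
    collateral findings elsewhere in the pipeline."""
    entry, _ = generate_entry(FixtureSpec(seed=40, extended=True))
    # validation defect: still parses, still cross-format consistent
    mutated, _ = inject_defect(entry, "null_item_value", seed=40)
    text = fileio.write_mwtab(mutated)
    reparsed = fileio.parse_mwtab(text)
    assert validator.validate_entry(reparsed).codes() == ["null_item_value"]
    json_side = fileio.parse_json(fileio.write_json(mutated))
    assert compare_entries(reparsed, json_side) == []
    # crossformat defect: both sides still parse and validate cleanly
    pair = (reparsed, json_side)
    (a, b), _ = inject_defect(
        (fileio.parse_mwtab(fileio.write_mwtab(entry)),
         fileio.parse_json(fileio.write_json(entry))),
        "item_values_mismatch", seed=40)
    assert not validator.validate_entry(a)
    assert not validator.validate_entry(b)
    assert {f.code for f in compare_entries(a, b)} == {"item_values_mismatch"}
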