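"""REST URL grammar, ID enumeration and bulk download over a mock transport."""

import json

import pytest

from mwkit import fileio
from mwkit.errors import ParameterError, RetrievalError
from mwkit.mwrest import (
    MockTransport,
    analysis_listing_url,
    build_url,
    download_all,
    enumerate_analysis_ids,
    generate_entry_urls,
    parse_url,
)
from tests.conftest import make_entry

BASE = "https://www.metabolomicsworkbench.org/rest/"


def test_study_context_url_renders_documented_path():
    rest_url = build_url({
        "context": "study",
        "input_item": "analysis_id",
        "input_value": "AN000002",
        "output_item": "mwtab",
        "output_format": "txt",
    })
    assert rest_url.url == BASE + "study/analysis_id/AN000002/mwtab/txt"


def test_study_id_json_variant():
    rest_url = build_url({
        "context": "study",
        "input_item": "study_id",
        "input_value": "ST000001",
        "output_item": "mwtab",
        "output_format": "json",
    })
    assert rest_url.url == BASE + "study/study_id/ST000001/mwtab/json"


def test_compound_context_url():
    rest_url = build_url({
        "context": "compound",
        "input_item": "formula",
        "input_value": "C20H34O11",
        "output_item": "all",
        "output_format": "txt",
    })
    assert rest_url.url == BASE + "compound/formula/C20H34O11/all/txt"


def test_render_parse_bijection():
    params = {
        "context": "study",
        "input_item": "analysis_id",
        "input_value": "AN000002",
        "output_item": "mwtab",
        "output_format": "txt",
    }
    assert parse_url(build_url(params).url) == params


@pytest.mark.parametrize("bad", [
    {"context": "bogus", "input_item": "analysis_id",
     "input_value": "AN000001", "output_item": "mwtab"},
    {"context": "study", "input_item": "formula",
     "input_value": "AN000001", "output_item": "mwtab"},
    {"context": "study", "input_item": "analysis_id",
     "input_value": "AN000001", "output_item": "everything"},
    {"context": "study", "input_item": "analysis_id", "output_item": "mwtab"},
])
def test_invalid_parameters_fail_closed(bad):
    with pytest.raises(ParameterError):
        build_url(bad)


def test_strict_false_allows_unknown_combinations():
    rest_url = build_url({
        "context": "refmet", "input_item": "name", "input_value": "Cholesterol",
        "output_item": "all", "output_format": "txt",
    }, strict=False)
    assert rest_url.url.endswith("refmet/name/Cholesterol/all/txt")


def test_generate_entry_urls_pick_input_item_by_id_kind():
    urls = list(generate_entry_urls(["AN000003", "ST000001"]))
    assert urls[0].input_item == "analysis_id"
    assert urls[1].input_item == "study_id"
    assert all(u.output_item == "mwtab" for u in urls)
    assert list(generate_entry_urls([])) == []
    with pytest.raises(ParameterError):
        list(generate_entry_urls(["XX123"]))


@pytest.mark.parametrize("body", [
    "AN000002\nAN000001\nAN000002\n",
    json.dumps({"1": {"analysis_id": "AN000002"},
                "2": {"analysis_id": "AN000001"},
                "3": {"analysis_id": "AN000002"}}),
])
def test_enumerate_analysis_ids_accepts_both_shapes(body):
    transport = MockTransport({analysis_listing_url(): body})
    assert enumerate_analysis_ids(transport) == ["AN000001", "AN000002"]


def test_enumerate_empty_listing():
    transport = MockTransport({analysis_listing_url(): "nothing here"})
    assert enumerate_analysis_ids(transport) == []


def test_enumerate_failure_raises():
    with pytest.raises(RetrievalError):
        enumerate_analysis_ids(MockTransport())


def _corpus_transport(n=3, blank=()):
    responses = {}
    ids = []
    for i in range(n):
        entry, manifest = make_entry(seed=100 + i)
        identifier = manifest["analysis_id"]
        ids.append(identifier)
        url = next(generate_entry_urls([identifier])).url
        responses[url] = "" if identifier in blank else fileio.write_mwtab(entry)
    responses[analysis_listing_url()] = "\n".join(ids)
    return MockTransport(responses), ids


def test_download_all_saves_entries_and_manifest(tmp_path):
    transport, ids = _corpus_transport()
    manifest = download_all(transport, tmp_path)
    assert all(manifest.statuses[i] == "ok" for i in ids)
    for identifier in ids:
        assert (tmp_path / f"{identifier}.txt").stat().st_size > 0
    saved = json.loads((tmp_path / "manifest.json").read_text())
    assert saved == manifest.statuses


def test_download_all_records_blank_bodies(tmp_path):
    transport, ids = _corpus_transport(blank=("AN010001",))
    blank_ids = [i for i in ids if i == "AN010001"]
    manifest = download_all(transport, tmp_path)
    for identifier in ids:
        expected = "blank_body" if identifier in blank_ids else "ok"
        assert manifest.statuses[identifier] == expected


def test_download_all_resume_is_idempotent(tmp_path):
    transport, ids = _corpus_transport()
    download_all(transport, tmp_path)
    fetches_before = len(transport.calls)
    manifest = download_all(transport, tmp_path, resume=True)
    # only the listing is re-fetched; entry files are skipped
    assert len(transport.calls) == fetches_before + 1
    assert all(status == "ok" for status in manifest.statuses.values())
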