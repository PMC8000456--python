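"""Shared fixtures: synthetic entries generated at test time."""

from __future__ import annotations

import pytest

from mwkit import fileio
from mwkit.fixtures import FixtureSpec, generate_entry


@pytest.fixture
def ms_entry():
    """A clean MS entry plus its ground-truth manifest."""
    return generate_entry(FixtureSpec(seed=11, analysis_type="MS"))


@pytest.fixture
def ms_entry_extended():
    return generate_entry(FixtureSpec(seed=12, analysis_type="MS", extended=True))


@pytest.fixture
def nmr_targeted_entry():
    return generate_entry(FixtureSpec(seed=13, analysis_type="NMR-targeted"))


@pytest.fixture
def nmr_binned_entry():
    return generate_entry(FixtureSpec(seed=14, analysis_type="NMR-binned"))


@pytest.fixture
def entry_pair(ms_entry):
    """The same analysis parsed from its text and JSON serializations."""
    entry, _ = ms_entry
    text_entry = fileio.parse_mwtab(fileio.write_mwtab(entry))
    json_entry = fileio.parse_json(fileio.write_json(entry))
    return text_entry, json_entry


def make_entry(seed: int = 0, **kwargs):
    """Helper for tests that need many varied entries."""
    return generate_entry(FixtureSpec(seed=seed, **kwargs))
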