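"""Corpus search: metadata value harvesting and metabolite extraction.

``extract_metadata`` sweeps a stream of parsed entries and collects the
distinct values observed for given section metadata keys (useful for
building search vocabularies, e.g. every LAST_NAME in a corpus).

``extract_metabolites`` selects the entries satisfying a conjunction of
key-value matchers (exact string or regular expression on an item value,
addressed as ``PREFIX:KEY`` such as ``PR:LAST_NAME``) and returns their
metabolite measurements keyed by metabolite name with full provenance
(analysis ID, sample ids, values).
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Union

from .model import (
    MEASUREMENT_BLOCK_KINDS,
    PREFIX_TO_SECTION,
    DataBlock,
    MWTabEntry,
    Section,
)

Pattern = Union[str, re.Pattern]


@dataclass
class Matcher:
    """One key-value criterion on an entry's item sections.

    ``section_key`` is ``PREFIX:KEY`` (e.g. ``PR:LAST_NAME``,
    ``CH:CHROMATOGRAPHY_TYPE``); the predicate is an exact, case-sensitive
    string unless a compiled regular expression is given.
    """

    section_key: str
    predicate: Pattern

    def matches(self, entry: MWTabEntry) -> bool:
        prefix, _, key = self.section_key.partition(":")
        section_name = PREFIX_TO_SECTION.get(prefix, prefix)
        content = entry.sections.get(section_name)
        if not isinstance(content, Section) or key not in content.items:
            return False
        value = content.items[key]
        if isinstance(self.predicate, re.Pattern):
            return self.predicate.search(value) is not None
        return value == self.predicate


def generate_matchers(pairs: Iterable[tuple[str, Pattern]]) -> list[Matcher]:
    """Build matchers from (section_key, value-or-regex) pairs."""
    return [Matcher(section_key=key, predicate=value) for key, value in pairs]


def _iter_item_values(entry: MWTabEntry, key: str):
    """Yield values for ``key``: 'PREFIX:KEY' addresses one section, a bare
    key is searched across every item section."""
    if ":" in key:
        prefix, _, bare = key.partition(":")
        section = entry.sections.get(PREFIX_TO_SECTION.get(prefix, prefix))
        if isinstance(section, Section) and bare in section.items:
            yield section.items[bare]
        return
    for content in entry.sections.values():
        if isinstance(content, Section) and key in content.items:
            yield content.items[key]


def extract_metadata(entries: Union[MWTabEntry, Iterable[MWTabEntry]],
                     *keys: str) -> dict[str, set[str]]:
    """Collect the distinct values for each key across the entries.

    Keys absent everywhere map to the empty set.
    """
    if isinstance(entries, MWTabEntry):
        entries = [entries]
    result: dict[str, set[str]] = {key: set() for key in keys}
    for entry in entries:
        for key in keys:
            result[key].update(_iter_item_values(entry, key))
    return result


def extract_metabolites(entries: Iterable[MWTabEntry],
                        matchers: Iterable[Matcher],
                        source: str = "data",
                        name_normalizer: Callable[[str], str] | None = None,
                        ) -> dict[str, dict[str, dict[str, str]]]:
    """Extract metabolite records from the entries satisfying ALL matchers.

    With ``source="data"`` (default) values come from the measurement blocks
    (metabolite -> analysis ID -> {sample id: value}); with
    ``source="metabolites"`` they come from the METABOLITES metadata table
    (metabolite -> analysis ID -> {heading: value}).  Metabolite names are
    used verbatim unless a ``name_normalizer`` hook is supplied.
    """
    matchers = list(matchers)
    normalize = name_normalizer or (lambda name: name)
    result: dict[str, dict[str, dict[str, str]]] = {}
    for entry in entries:
        if not all(m.matches(entry) for m in matchers):
            continue
        entry_id = entry.analysis_id or entry.study_id or "unknown"
        if source == "data":
            blocks = [c for c in entry.sections.values()
                      if isinstance(c, DataBlock)
                      and c.kind in MEASUREMENT_BLOCK_KINDS]
        elif source == "metabolites":
            block = entry.sections.get("METABOLITES")
            blocks = [block] if isinstance(block, DataBlock) else []
        else:
            raise ValueError(f"unknown extraction source: {source!r}")
        for block in blocks:
            for row in block.rows:
                record = result.setdefault(normalize(row.label), {})
                record.setdefault(entry_id, {}).update(row.values)
    return result


def metabolites_to_json(result: dict[str, dict[str, dict[str, str]]]) -> str:
    """Nested, provenance-preserving JSON export."""
    return json.dumps(result, indent=1, sort_keys=True)


def metabolites_to_csv(result: dict[str, dict[str, dict[str, str]]]) -> str:
    """Wide CSV export: one row per metabolite, one column per
    (analysis, sample) pair."""
    columns: list[tuple[str, str]] = sorted({
        (entry_id, sample)
        for per_entry in result.values()
        for entry_id, samples in per_entry.items()
        for sample in samples
    })
    out = io.StringIO()
    writer = csv.writer(out)
    writer.writerow(["metabolite"] + [f"{e}:{s}" for e, s in columns])
    for name in sorted(result):
        row = [name]
        for entry_id, sample in columns:
            row.append(result[name].get(entry_id, {}).get(sample, ""))
        writer.writerow(row)
    return out.getvalue()


def metadata_to_csv(result: dict[str, set[str]]) -> str:
    out = io.StringIO()
    writer = csv.writer(out)
    writer.writerow(["key", "value"])
    for key in sorted(result):
        for value in sorted(result[key]):
            writer.writerow([key, value])
    return out.getvalue()


def metadata_to_json(result: dict[str, set[str]]) -> str:
    return json.dumps({k: sorted(v) for k, v in result.items()},
                      indent=1, sort_keys=True)
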