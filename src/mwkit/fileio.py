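"""Readers and writers for the two entry serializations.

``parse_mwtab`` / ``write_mwtab`` handle the tab-delimited text form,
``parse_json`` / ``write_json`` the JSON mirror of the same ordered-section
structure.  Parse failures raise :class:`~mwkit.errors.ParseError` with a
machine-readable defect code and line locus; the codes follow the observed
failure taxonomy for repository entries (malformed SUBJECT_SAMPLE_FACTORS
records, section headers missing their ``#`` prefix, broken VERSION lines,
duplicated items, bad ANALYSIS_TYPE lines, missing tab delimiters, tab runs
inside the banner, and files missing the banner entirely).

``read_entries`` dispatches paths, directories and REST URLs (through an
injectable transport) and auto-detects the serialization from the first
non-blank characters.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Union

from . import config
from .errors import ParseError, RetrievalError, SerializationError
from .model import (
    DATA_BLOCK_KINDS,
    EXTENDED_BLOCK_KINDS,
    HEADER_ID_PATTERNS,
    ITEM_SECTION_NAMES,
    MEASUREMENT_BLOCK_KINDS,
    SECTION_PREFIXES,
    SSF_SECTION_NAME,
    CANONICAL_SECTION_NAMES,
    DataBlock,
    MWTabEntry,
    Row,
    Section,
    SubjectSampleFactor,
    SubjectSampleFactorList,
    resolve_section_name,
)
from .tokenizer import (
    BANNER_PREFIX,
    Line,
    classify_header_banner,
    item_key_value,
    tokenize,
)

#: Parse-defect classes raised by :func:`parse_mwtab`.
TEXT_PARSE_DEFECT_CLASSES = (
    "ssf_malformed",
    "missing_hash_prefix",
    "version_line",
    "duplicate_item",
    "analysis_type_line",
    "missing_tab",
    "excessive_tabs",
    "missing_banner",
)

_ITEM_KEY_NO_TAB_RE = re.compile(r"^[A-Z]{2,}:[A-Za-z0-9_]+[ ]")
_FACTOR_SEP = " | "
_ADDITIONAL_SEP = "; "


def _parse_factor_string(text: str) -> dict[str, str]:
    factors: dict[str, str] = {}
    if not text.strip():
        return factors
    for chunk in text.split("|"):
        name, _, value = chunk.strip().partition(":")
        factors[name.strip()] = value.strip()
    return factors


def _parse_additional_string(text: str) -> dict[str, str]:
    pairs: dict[str, str] = {}
    if not text.strip():
        return pairs
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        pairs[key.strip()] = value.strip()
    return pairs


def _render_factors(factors: dict[str, str]) -> str:
    return _FACTOR_SEP.join(f"{k}:{v}" for k, v in factors.items())


def _render_additional(additional: dict[str, str]) -> str:
    return _ADDITIONAL_SEP.join(f"{k}={v}" for k, v in additional.items())


def _build_block(kind: str, rows: list[Line], units: str | None) -> DataBlock:
    if not rows:
        return DataBlock(kind=kind, units=units)
    header = rows[0]
    label_header = header.fields[0]
    body = rows[1:]
    block = DataBlock(kind=kind, units=units, label_header=label_header)
    if kind in MEASUREMENT_BLOCK_KINDS:
        block.sample_ids = list(header.fields[1:])
        if body and body[0].fields[0] == "Factors":
            block.factor_row = list(body[0].fields[1:])
            body = body[1:]
        width = len(block.sample_ids)
        columns = block.sample_ids
    else:  # METABOLITES and EXTENDED_* carry metadata headings
        block.headings = list(header.fields[1:])
        width = len(block.headings)
        columns = block.headings
    for line in body:
        cells = line.fields
        if len(cells) != width + 1:
            raise ParseError(
                "block_row_width", line.number,
                f"{kind} row has {len(cells) - 1} values, expected {width}",
            )
        block.rows.append(Row(label=cells[0], values=dict(zip(columns, cells[1:]))))
    return block


def parse_mwtab(text: str) -> MWTabEntry:
    """Parse one mwTab text serialization into an :class:`MWTabEntry`.

    Raises :class:`ParseError` with a taxonomy code and line number on any
    structural defect; never returns a partially-parsed entry.
    """
    if text.strip() == "":
        raise ParseError("empty_file", 0, "file body is blank")
    lines = tokenize(text)
    non_blank = [ln for ln in lines if ln.kind != "blank"]
    banner = non_blank[0]
    if banner.kind != "header_banner":
        raise ParseError("missing_banner", banner.number,
                         "file does not begin with the METABOLOMICS WORKBENCH banner")
    if "\t" in banner.raw:
        raise ParseError("excessive_tabs", banner.number,
                         "tab characters inside the banner line")
    header_ids, _ = classify_header_banner(banner)
    for kind, value in header_ids.items():
        pattern = HEADER_ID_PATTERNS.get(kind)
        if pattern and not re.fullmatch(pattern, value):
            raise ParseError("bad_header_id", banner.number,
                             f"malformed {kind}: {value!r}")

    version = ""
    created_on = ""
    sections: dict[str, object] = {}
    context: str | None = None       # canonical name of the open section
    current_items: Section | None = None
    in_header = True
    pending_units: dict[str, str] = {}
    block_kind: str | None = None
    block_rows: list[Line] = []

    for ln in lines[lines.index(banner) + 1:]:
        kind = ln.kind
        if kind in ("blank", "end_marker"):
            continue
        if kind == "header_banner":
            raise ParseError("malformed_line", ln.number, "duplicate banner line")
        if kind == "section_header":
            name = resolve_section_name(ln.fields[0])
            in_header = False
            if name in sections or (name in DATA_BLOCK_KINDS and name == block_kind):
                raise ParseError("duplicate_section", ln.number,
                                 f"section {name} appears twice")
            if name in ITEM_SECTION_NAMES:
                current_items = Section(name=name)
                sections[name] = current_items
                context = name
            elif name == SSF_SECTION_NAME:
                sections[name] = SubjectSampleFactorList()
                context = name
            elif name in DATA_BLOCK_KINDS:
                context = name           # block container; content follows
                current_items = None
            else:
                current_items = Section(name=name, known=False)
                sections[name] = current_items
                context = name
        elif kind == "item":
            key, value = item_key_value(ln)
            if in_header:
                if key == "VERSION":
                    if not value.strip():
                        raise ParseError("version_line", ln.number,
                                         "VERSION line has no value")
                    version = value
                elif key == "CREATED_ON":
                    created_on = value
                else:
                    raise ParseError("malformed_line", ln.number,
                                     f"unexpected header-region line: {key!r}")
                continue
            if current_items is None:
                raise ParseError("malformed_line", ln.number,
                                 f"item line outside an item section: {key!r}")
            bare = key.split(":", 1)[1] if ":" in key else key
            if bare in current_items.items:
                raise ParseError("duplicate_item", ln.number,
                                 f"duplicate item {key} in {current_items.name}")
            if current_items.name == "ANALYSIS" and bare == "ANALYSIS_TYPE" \
                    and value not in ("MS", "NMR"):
                raise ParseError("analysis_type_line", ln.number,
                                 f"invalid ANALYSIS_TYPE value: {value!r}")
            current_items.items[bare] = value
        elif kind == "ssf_record":
            cells = ln.fields
            if len(cells) != 5:
                raise ParseError("ssf_malformed", ln.number,
                                 f"SUBJECT_SAMPLE_FACTORS record has {len(cells) - 1} "
                                 "fields, expected 4")
            record = SubjectSampleFactor(
                subject_id=cells[1],
                sample_id=cells[2],
                factors=_parse_factor_string(cells[3]),
                additional=_parse_additional_string(cells[4]),
            )
            ssf = sections.get(SSF_SECTION_NAME)
            if not isinstance(ssf, SubjectSampleFactorList):
                raise ParseError("malformed_line", ln.number,
                                 "SUBJECT_SAMPLE_FACTORS record outside its section")
            ssf.append(record)
        elif kind == "units_line":
            name = ln.fields[0][: -len(":UNITS")]
            pending_units[resolve_section_name(name)] = ln.fields[1] if len(ln.fields) > 1 else ""
        elif kind == "block_start":
            block_kind = resolve_section_name(ln.fields[0])
            if block_kind in sections:
                raise ParseError("duplicate_section", ln.number,
                                 f"block {block_kind} appears twice")
            block_rows = []
            in_header = False
        elif kind == "block_row":
            block_rows.append(ln)
        elif kind == "block_end":
            assert block_kind is not None
            sections[block_kind] = _build_block(
                block_kind, block_rows, pending_units.get(block_kind))
            block_kind = None
            block_rows = []
        else:  # malformed
            cell = ln.raw.rstrip("\r").strip()
            if in_header and cell.startswith("VERSION"):
                raise ParseError("version_line", ln.number,
                                 "VERSION line is not tab-delimited")
            if _ITEM_KEY_NO_TAB_RE.match(cell):
                raise ParseError("missing_tab", ln.number,
                                 f"missing tab delimiter in item line: {cell.split()[0]}")
            if resolve_section_name(cell) in CANONICAL_SECTION_NAMES:
                raise ParseError("missing_hash_prefix", ln.number,
                                 f"section header {cell!r} is missing its '#' prefix")
            raise ParseError("malformed_line", ln.number, f"unclassifiable line: {cell!r}")

    if block_kind is not None:
        raise ParseError("malformed_line", len(lines),
                         f"block {block_kind} was never closed")
    return MWTabEntry(header_ids=header_ids, version=version, created_on=created_on,
                      sections=sections, source_format="mwtab_text")


def write_mwtab(entry: MWTabEntry) -> str:
    """Render an entry in the tab-delimited text serialization."""
    out: list[str] = []
    banner = BANNER_PREFIX
    tokens = " ".join(f"{k}:{v}" for k, v in entry.header_ids.items())
    if tokens:
        banner += " " + tokens
    out.append(banner)
    if entry.version:
        out.append(f"VERSION\t{entry.version}")
    if entry.created_on:
        out.append(f"CREATED_ON\t{entry.created_on}")
    previous: str | None = None
    for name, content in entry.sections.items():
        if isinstance(content, Section):
            out.append(f"#{name}")
            prefix = SECTION_PREFIXES.get(name)
            for key, value in content.items.items():
                full = f"{prefix}:{key}" if prefix and content.known else key
                out.append(f"{full}\t{value}")
        elif isinstance(content, SubjectSampleFactorList):
            out.append(f"#{SSF_SECTION_NAME}")
            for record in content:
                out.append("\t".join([
                    SSF_SECTION_NAME,
                    record.subject_id,
                    record.sample_id,
                    _render_factors(record.factors),
                    _render_additional(record.additional),
                ]))
        elif isinstance(content, DataBlock):
            # EXTENDED_* blocks nest inside the preceding #METABOLITES section
            nested = (content.kind in EXTENDED_BLOCK_KINDS
                      and previous in ("METABOLITES",) + EXTENDED_BLOCK_KINDS)
            if not nested:
                out.append(f"#{name}")
            if content.units is not None:
                out.append(f"{content.kind}:UNITS\t{content.units}")
            out.append(f"{content.kind}_START")
            if content.kind in MEASUREMENT_BLOCK_KINDS:
                header = content.label_header or "Samples"
                out.append("\t".join([header] + content.sample_ids))
                if content.factor_row is not None:
                    out.append("\t".join(["Factors"] + content.factor_row))
                columns = content.sample_ids
            else:
                header = content.label_header or "metabolite_name"
                out.append("\t".join([header] + content.headings))
                columns = content.headings
            for row in content.rows:
                try:
                    cells = [row.label] + [row.values[c] for c in columns]
                except KeyError as exc:
                    raise SerializationError(
                        f"row {row.label!r} in {content.kind} lacks a value for "
                        f"column {exc.args[0]!r}") from exc
                out.append("\t".join(cells))
            out.append(f"{content.kind}_END")
        else:  # pragma: no cover - defensive
            raise SerializationError(f"unserializable section content: {name}")
        previous = name
    out.append("#END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# JSON serialization

def _json_section_payload(content, keys: dict[str, str]):
    if isinstance(content, Section):
        return dict(content.items)
    if isinstance(content, SubjectSampleFactorList):
        return [
            {
                keys["subject_id"]: r.subject_id,
                keys["sample_id"]: r.sample_id,
                keys["factors"]: dict(r.factors),
                keys["additional"]: dict(r.additional),
            }
            for r in content
        ]
    block: DataBlock = content
    payload: dict[str, object] = {}
    if block.units is not None:
        payload[keys["units"]] = block.units
    if block.kind in MEASUREMENT_BLOCK_KINDS:
        columns = block.sample_ids
    else:
        payload[keys["fields"]] = list(block.headings)
        columns = block.headings
    if block.factor_row is not None:
        payload[keys["factor_row"]] = list(block.factor_row)
    payload[keys["data"]] = [
        {keys["metabolite"]: row.label, **{c: row.values[c] for c in columns}}
        for row in block.rows
    ]
    return payload


def write_json(entry: MWTabEntry, keys: dict[str, str] | None = None) -> str:
    """Render an entry in the JSON serialization (deterministic key order ==
    section order)."""
    keys = keys or config.JSON_KEYS
    banner: dict[str, str] = dict(entry.header_ids)
    if entry.version:
        banner[keys["version"]] = entry.version
    if entry.created_on:
        banner[keys["created_on"]] = entry.created_on
    doc: dict[str, object] = {keys["banner"]: banner}
    for name, content in entry.sections.items():
        doc[name] = _json_section_payload(content, keys)
    return json.dumps(doc, indent=1, ensure_ascii=False) + "\n"


def _block_from_json(kind: str, payload, keys: dict[str, str]) -> DataBlock:
    if not isinstance(payload, dict):
        raise ParseError("wrong_structure", 0,
                         f"section {kind} is a {type(payload).__name__}, expected an object")
    units = payload.get(keys["units"])
    data = payload.get(keys["data"], [])
    if not isinstance(data, list):
        raise ParseError("wrong_structure", 0, f"{kind} {keys['data']} is not an array")
    block = DataBlock(kind=kind, units=units)
    if kind in MEASUREMENT_BLOCK_KINDS:
        block.label_header = "Samples"
        for row_payload in data:
            columns = [c for c in row_payload if c != keys["metabolite"]]
            if not block.sample_ids:
                block.sample_ids = columns
            block.rows.append(Row(
                label=row_payload.get(keys["metabolite"], ""),
                values={c: row_payload[c] for c in columns},
            ))
        factor_row = payload.get(keys["factor_row"])
        if factor_row is not None:
            block.factor_row = list(factor_row)
    else:
        block.label_header = "metabolite_name"
        block.headings = list(payload.get(keys["fields"], []))
        for row_payload in data:
            block.rows.append(Row(
                label=row_payload.get(keys["metabolite"], ""),
                values={c: row_payload.get(c, "") for c in block.headings},
            ))
    return block


def parse_json(text: str, keys: dict[str, str] | None = None) -> MWTabEntry:
    """Parse the JSON serialization into an :class:`MWTabEntry`.

    Raises ``ParseError`` with code ``json_syntax`` on malformed JSON,
    ``missing_banner`` when the banner object is absent, and
    ``wrong_structure`` when a section has the wrong shape (e.g. a list
    where an object is expected).
    """
    if text.strip() == "":
        raise ParseError("empty_file", 0, "file body is blank")
    keys = keys or config.JSON_KEYS
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError("json_syntax", exc.lineno, str(exc)) from exc
    if not isinstance(doc, dict):
        raise ParseError("wrong_structure", 0, "top level is not an object")
    if keys["banner"] not in doc:
        raise ParseError("missing_banner", 0,
                         "JSON document lacks the METABOLOMICS WORKBENCH object")
    banner = doc[keys["banner"]]
    if not isinstance(banner, dict):
        raise ParseError("wrong_structure", 0, "banner section is not an object")
    header_ids = {k: v for k, v in banner.items()
                  if k not in (keys["version"], keys["created_on"])}
    for kind, value in header_ids.items():
        pattern = HEADER_ID_PATTERNS.get(kind)
        if pattern and not re.fullmatch(pattern, value):
            raise ParseError("bad_header_id", 0, f"malformed {kind}: {value!r}")
    sections: dict[str, object] = {}
    for name, payload in doc.items():
        if name == keys["banner"]:
            continue
        canonical = resolve_section_name(name)
        if canonical in ITEM_SECTION_NAMES:
            if not isinstance(payload, dict):
                raise ParseError(
                    "wrong_structure", 0,
                    f"section {canonical} is a {type(payload).__name__}, "
                    "expected an object")
            sections[canonical] = Section(name=canonical,
                                          items={k: str(v) for k, v in payload.items()})
        elif canonical == SSF_SECTION_NAME:
            if not isinstance(payload, list):
                raise ParseError("wrong_structure", 0,
                                 f"{SSF_SECTION_NAME} is not an array")
            records = SubjectSampleFactorList()
            for item in payload:
                records.append(SubjectSampleFactor(
                    subject_id=item.get(keys["subject_id"], "-"),
                    sample_id=item.get(keys["sample_id"], ""),
                    factors=dict(item.get(keys["factors"], {})),
                    additional=dict(item.get(keys["additional"], {})),
                ))
            sections[canonical] = records
        elif canonical in DATA_BLOCK_KINDS:
            sections[canonical] = _block_from_json(canonical, payload, keys)
        else:
            if not isinstance(payload, dict):
                raise ParseError(
                    "wrong_structure", 0,
                    f"section {name} is a {type(payload).__name__}, expected an object")
            sections[name] = Section(name=name, known=False,
                                     items={k: str(v) for k, v in payload.items()})
    return MWTabEntry(
        header_ids=header_ids,
        version=str(banner.get(keys["version"], "")),
        created_on=str(banner.get(keys["created_on"], "")),
        sections=sections,
        source_format="json",
    )


# ---------------------------------------------------------------------------
# Source dispatch

@dataclass
class RawRestFile:
    """A REST response body that is not an mwTab entry (csv, json listings,
    plain text); stored verbatim with its source URL."""

    source: str
    text: str


@dataclass
class EntryError:
    """Per-source failure yielded by :func:`read_entries` instead of a
    silent skip."""

    source: str
    error: Exception


def detect_format(text: str) -> str:
    """Return ``"mwtab_text"`` or ``"json"`` from the first non-blank
    characters; ambiguous bodies raise ``ParseError('detection')``."""
    stripped = text.lstrip()
    if stripped.startswith(BANNER_PREFIX) or stripped.startswith("#"):
        return "mwtab_text"
    if stripped.startswith("{"):
        return "json"
    raise ParseError("detection", 1, "cannot detect serialization format")


def parse_any(text: str) -> MWTabEntry:
    if text.strip() == "":
        raise ParseError("empty_file", 0, "file body is blank")
    if detect_format(text) == "json":
        return parse_json(text)
    return parse_mwtab(text)


def _is_url(source: str) -> bool:
    return source.startswith(("http://", "https://"))


def read_entries(sources: Iterable[Union[str, Path]], transport=None,
                 encoding: str = "utf-8",
                 ) -> Iterator[Union[MWTabEntry, EntryError]]:
    """Lazily parse entries from paths, directories or URLs.

    Directories expand to their ``*.txt`` / ``*.json`` entry files in name
    order.  URLs are fetched through ``transport`` (an object with
    ``fetch(url) -> (status, body)``).  Per-source failures are yielded as
    :class:`EntryError` records, never silently skipped.
    """
    for source in sources:
        source = str(source)
        if _is_url(source):
            try:
                body = fetch_url(source, transport)
                yield parse_any(body)
            except Exception as exc:  # noqa: BLE001 - reported, not raised
                yield EntryError(source=source, error=exc)
        elif os.path.isdir(source):
            names = sorted(
                p for p in os.listdir(source)
                if p.endswith((".txt", ".json")) and not p.startswith("manifest"))
            yield from read_entries(
                (os.path.join(source, name) for name in names),
                transport=transport, encoding=encoding)
        else:
            try:
                with open(source, encoding=encoding) as handle:
                    yield parse_any(handle.read())
            except Exception as exc:  # noqa: BLE001
                yield EntryError(source=source, error=exc)


def fetch_url(url: str, transport=None) -> str:
    """Fetch ``url`` through ``transport`` and return the body text."""
    if transport is None:
        from .mwrest import HttpTransport
        transport = HttpTransport()
    status, body = transport.fetch(url)
    if status != 200:
        raise RetrievalError(url, status)
    return body


def read_raw(url: str, transport=None) -> RawRestFile:
    """Download a REST response that cannot be represented as an mwTab entry
    and return it untouched."""
    return RawRestFile(source=url, text=fetch_url(url, transport))
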