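"""Editable configuration tables.

Everything here is data, not code: the required-section schema, the
null-value token set, the JSON dialect key spellings, the heading
standardization rule battery and the REST validity table all ship as plain
structures that can be dumped to / loaded from JSON so repositories can
adapt them without touching the implementation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

#: Item values treated as null by the validator.
NULL_TOKENS: tuple[str, ...] = ("", "NA", "N/A", "-")

#: Tokens allowed inside numeric measurement data as "missing".  Strictest
#: reading: only the empty cell.
NUMERIC_MISSING_TOKENS: tuple[str, ...] = ("",)

#: JSON dialect key spellings (overridable).
JSON_KEYS: dict[str, str] = {
    "banner": "METABOLOMICS WORKBENCH",
    "version": "VERSION",
    "created_on": "CREATED_ON",
    "subject_id": "Subject ID",
    "sample_id": "Sample ID",
    "factors": "Factors",
    "additional": "Additional sample data",
    "units": "Units",
    "data": "Data",
    "fields": "Fields",
    "metabolite": "Metabolite",
    "factor_row": "Factor row",
}

#: Default schema: required sections (always + per analysis type) and
#: required items per section.  CHROMATOGRAPHY is required only for MS
#: analyses; NMR analyses require the NMR section instead of MS.
DEFAULT_SCHEMA: dict[str, Any] = {
    "version": "1.0",
    "required_sections": [
        "PROJECT",
        "STUDY",
        "SUBJECT",
        "COLLECTION",
        "TREATMENT",
        "SAMPLEPREP",
        "ANALYSIS",
        "SUBJECT_SAMPLE_FACTORS",
    ],
    "required_sections_ms": ["CHROMATOGRAPHY", "MS"],
    "required_sections_nmr": ["NMR"],
    "required_items": {
        "PROJECT": ["PROJECT_TITLE", "FIRST_NAME", "LAST_NAME", "INSTITUTE"],
        "STUDY": ["STUDY_TITLE", "FIRST_NAME", "LAST_NAME", "INSTITUTE"],
        "SUBJECT": ["SUBJECT_TYPE", "SUBJECT_SPECIES"],
        "COLLECTION": ["COLLECTION_SUMMARY"],
        "TREATMENT": ["TREATMENT_SUMMARY"],
        "SAMPLEPREP": ["SAMPLEPREP_SUMMARY"],
        "CHROMATOGRAPHY": ["CHROMATOGRAPHY_TYPE", "COLUMN_NAME", "INSTRUMENT_NAME"],
        "ANALYSIS": ["ANALYSIS_TYPE"],
        "MS": ["INSTRUMENT_NAME", "INSTRUMENT_TYPE", "MS_TYPE", "ION_MODE"],
        "NMR": ["INSTRUMENT_NAME", "INSTRUMENT_TYPE"],
    },
}

#: Heading standardization rule battery for METABOLITES metadata headings.
#: ``patterns`` use the printed-style "{,}" quantifier, normalized to "*" at
#: load time.  Lower precedence rank is tried first, so the more specific
#: rule (retention_index, moverz_quant) wins when a broader one also matches.
DEFAULT_HEADING_RULES: list[dict[str, Any]] = [
    {"canonical": "moverz_quant", "precedence": 0, "patterns": [
        r"(?i)(moverz)(\s|_)(quant)",
        r"(?i)(quan)[\S]{,}(\s|_)(m)[\S]{,}(z)",
    ]},
    {"canonical": "retention_index", "precedence": 1, "patterns": [
        r"(?i)(ri)$",
        r"(?i)(ret)[\s|\S]{,}(index)",
    ]},
    {"canonical": "hmdb_id", "precedence": 10, "patterns": [
        r"(?i)[\s|\S]{,}(HMDB)",
        r"(?i)(Human Metabolome D)[\S]{,}",
    ]},
    {"canonical": "inchi_key", "precedence": 11, "patterns": [
        r"(?i)(inchi)[\S]{,}",
    ]},
    {"canonical": "kegg_id", "precedence": 12, "patterns": [
        r"(?i)(kegg)$",
        r"(?i)(kegg)(\s|_)(i)",
    ]},
    {"canonical": "moverz", "precedence": 13, "patterns": [
        r"(?i)(m/z)",
        r"(?i)(moverz)$",
    ]},
    {"canonical": "other_id", "precedence": 14, "patterns": [
        r"(?i)(other)(\s|_)(id)$",
    ]},
    {"canonical": "pubchem_id", "precedence": 15, "patterns": [
        r"(?i)(pubchem)[\S]{,}",
    ]},
    {"canonical": "retention_time", "precedence": 20, "patterns": [
        r"(?i)(r)[\s|\S]{,}(time)[\S]{,}",
    ]},
]

#: Documented REST root.
REST_BASE_URL = "https://www.metabolomicsworkbench.org/rest/"

#: Valid (context, input_item, output_item) combinations, seeded from the
#: demonstrated usages.  Unknown combinations fail closed unless the caller
#: passes strict=False.
REST_VALIDITY_TABLE: dict[str, dict[str, Any]] = {
    "study": {
        "input_items": ["analysis_id", "study_id"],
        "output_items": ["mwtab"],
        "output_formats": ["txt", "json"],
    },
    "compound": {
        "input_items": ["formula"],
        "output_items": ["all"],
        "output_formats": ["txt", "json"],
    },
}

#: Path (relative to the REST base) whose body lists the available analysis
#: IDs; the response may be plain text or JSON — both shapes are accepted.
REST_ANALYSIS_LISTING_PATH = "study/study_id/ST/available"


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a JSON config overlay (schema, heading rules, REST table)."""
    with open(path, encoding="utf-8") as handle:
        return json.load(handle)


def dump_default_config(path: str | Path) -> None:
    """Write the shipped defaults to ``path`` as editable JSON."""
    payload = {
        "null_tokens": list(NULL_TOKENS),
        "numeric_missing_tokens": list(NUMERIC_MISSING_TOKENS),
        "json_keys": JSON_KEYS,
        "schema": DEFAULT_SCHEMA,
        "heading_rules": DEFAULT_HEADING_RULES,
        "rest_base_url": REST_BASE_URL,
        "rest_validity_table": REST_VALIDITY_TABLE,
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
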