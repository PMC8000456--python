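"""Entry validation: schema conformance, null values, sample-ID and
metabolite-name consistency, numeric measurement data, and the
data-presence rule.

Validation never stops at the first problem: every checker runs and the
union of findings is returned as a :class:`ValidationReport`, so a single
pass over a corpus yields the complete defect census for each file.

The five checkers are:

1. sample consistency — no blank sample ids or factor values in
   SUBJECT_SAMPLE_FACTORS, and every sample id appearing in a measurement
   block (or an EXTENDED_* block) is declared in SUBJECT_SAMPLE_FACTORS
   (the declared set may be a superset: some declared samples may carry no
   processed data);
2. metabolite consistency — no blank metabolite names, and the name sets of
   the measurement block and the METABOLITES table coincide;
3. numeric data — every cell of MS processed data is a decimal numeral
   (optional sign/scientific notation) or an allowed missing-value token;
4. schema — each required section is present with its required items;
5. data presence — an MS entry with no measurement block must at least point
   at a results file via an MS_RESULTS_FILE item; NMR entries have no such
   escape hatch, so a data-less NMR entry is always flagged.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Any

from . import config
from .model import (
    EXTENDED_BLOCK_KINDS,
    MEASUREMENT_BLOCK_KINDS,
    SSF_SECTION_NAME,
    DataBlock,
    MWTabEntry,
    Section,
    SubjectSampleFactorList,
)

FINDING_CODES = (
    "schema_missing_section",
    "schema_missing_item",
    "null_item_value",
    "ssf_null_field",
    "sample_id_inconsistent",
    "sample_id_inconsistent_extended",
    "metabolite_name_blank",
    "metabolite_name_inconsistent",
    "non_numeric_data",
    "missing_data_no_results_file",
)

_NUMERIC_RE = re.compile(r"[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?")


@dataclass(frozen=True)
class Finding:
    """One typed QC observation: defect code, section, locus (item key /
    sample id / metabolite name) and a human-readable message."""

    code: str
    section: str
    locus: str
    message: str = ""


@dataclass
class ValidationReport:
    """All findings gathered for one entry."""

    source: str = ""
    findings: list[Finding] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.findings)

    def __len__(self) -> int:
        return len(self.findings)

    def codes(self) -> list[str]:
        return [f.code for f in self.findings]

    def to_json(self) -> str:
        payload = [f.__dict__ for f in self.findings]
        return json.dumps({"source": self.source, "findings": payload}, indent=1)

    def to_tsv(self) -> str:
        lines = ["code\tsection\tlocus\tmessage"]
        lines += [f"{f.code}\t{f.section}\t{f.locus}\t{f.message}"
                  for f in self.findings]
        return "\n".join(lines) + "\n"


@dataclass
class SchemaSpec:
    """Machine-checkable schema: required sections (plus per-analysis-type
    conditionals) and required items per section."""

    required_sections: list[str]
    required_sections_ms: list[str]
    required_sections_nmr: list[str]
    required_items: dict[str, list[str]]
    version: str = "1.0"

    @classmethod
    def default(cls) -> "SchemaSpec":
        return cls.from_dict(config.DEFAULT_SCHEMA)

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "SchemaSpec":
        return cls(
            required_sections=list(payload["required_sections"]),
            required_sections_ms=list(payload.get("required_sections_ms", [])),
            required_sections_nmr=list(payload.get("required_sections_nmr", [])),
            required_items={k: list(v) for k, v in payload["required_items"].items()},
            version=payload.get("version", "1.0"),
        )

    def sections_for(self, analysis_type: str) -> list[str]:
        required = list(self.required_sections)
        if analysis_type == "MS":
            required += self.required_sections_ms
        elif analysis_type == "NMR":
            required += self.required_sections_nmr
        return required


def _measurement_blocks(entry: MWTabEntry) -> list[DataBlock]:
    return [c for c in entry.sections.values()
            if isinstance(c, DataBlock) and c.kind in MEASUREMENT_BLOCK_KINDS]


def _extended_blocks(entry: MWTabEntry) -> list[DataBlock]:
    return [c for c in entry.sections.values()
            if isinstance(c, DataBlock) and c.kind in EXTENDED_BLOCK_KINDS]


def check_schema(entry: MWTabEntry, schema: SchemaSpec,
                 null_tokens: tuple[str, ...] = config.NULL_TOKENS,
                 ) -> list[Finding]:
    """Flag required sections and items that are absent.

    A required item carrying a null value counts as schema-missing too (and
    is additionally flagged by the null-value checker): one defect, two
    distinct codes.
    """
    findings: list[Finding] = []
    for name in schema.sections_for(entry.analysis_type):
        if name not in entry.sections:
            findings.append(Finding(
                code="schema_missing_section", section=name, locus=name,
                message=f"required section {name} is missing"))
    for name, keys in schema.required_items.items():
        content = entry.sections.get(name)
        if not isinstance(content, Section):
            continue
        for key in keys:
            if content.items.get(key, "").strip() in null_tokens:
                findings.append(Finding(
                    code="schema_missing_item", section=name, locus=key,
                    message=f"required item {key} missing or null in {name}"))
    return findings


def check_null_items(entry: MWTabEntry,
                     null_tokens: tuple[str, ...] = config.NULL_TOKENS,
                     ) -> list[Finding]:
    """Flag item values that are null tokens (empty, NA, N/A, dash)."""
    findings: list[Finding] = []
    for name, content in entry.sections.items():
        if not isinstance(content, Section):
            continue
        for key, value in content.items.items():
            if value.strip() in null_tokens:
                findings.append(Finding(
                    code="null_item_value", section=name, locus=key,
                    message=f"item {key} in {name} has a null value: {value!r}"))
    return findings


def check_sample_consistency(entry: MWTabEntry) -> list[Finding]:
    """Blank sample ids/factors, and sample ids used in measurement or
    EXTENDED_* blocks that are not declared in SUBJECT_SAMPLE_FACTORS."""
    findings: list[Finding] = []
    ssf = entry.sections.get(SSF_SECTION_NAME)
    if not isinstance(ssf, SubjectSampleFactorList):
        return findings
    declared: set[str] = set()
    for record in ssf:
        if not record.sample_id.strip():
            findings.append(Finding(
                code="ssf_null_field", section=SSF_SECTION_NAME,
                locus=record.subject_id,
                message="record has a blank sample id"))
        else:
            declared.add(record.sample_id)
        for factor, value in record.factors.items():
            if not value.strip():
                findings.append(Finding(
                    code="ssf_null_field", section=SSF_SECTION_NAME,
                    locus=record.sample_id,
                    message=f"factor {factor} is blank for sample {record.sample_id}"))
    for block in _measurement_blocks(entry):
        for sample_id in block.sample_ids:
            if sample_id not in declared:
                findings.append(Finding(
                    code="sample_id_inconsistent", section=block.kind,
                    locus=sample_id,
                    message=f"sample {sample_id} in {block.kind} is not declared "
                            "in SUBJECT_SAMPLE_FACTORS"))
    for block in _extended_blocks(entry):
        flagged: set[str] = set()
        for row in block.rows:
            sample_id = row.values.get("sample_id", "")
            if sample_id not in declared and sample_id not in flagged:
                flagged.add(sample_id)
                findings.append(Finding(
                    code="sample_id_inconsistent_extended", section=block.kind,
                    locus=sample_id,
                    message=f"sample {sample_id} in {block.kind} is not declared "
                            "in SUBJECT_SAMPLE_FACTORS"))
    return findings


def check_metabolite_consistency(entry: MWTabEntry) -> list[Finding]:
    """Blank metabolite names, and names present in only one of the
    measurement block and the METABOLITES table.

    Applies to MS files and targeted NMR files; binned NMR data has no
    per-metabolite table to cross-check.
    """
    findings: list[Finding] = []
    metabolites = entry.sections.get("METABOLITES")
    data_blocks = [b for b in _measurement_blocks(entry)
                   if b.kind != "NMR_BINNED_DATA"]
    for block in data_blocks + ([metabolites] if isinstance(metabolites, DataBlock) else []):
        for row in block.rows:
            if not row.label.strip():
                findings.append(Finding(
                    code="metabolite_name_blank", section=block.kind, locus="",
                    message=f"blank metabolite name in {block.kind}"))
    if isinstance(metabolites, DataBlock) and data_blocks:
        meta_names = {r.label for r in metabolites.rows if r.label.strip()}
        for block in data_blocks:
            data_names = {r.label for r in block.rows if r.label.strip()}
            for name in sorted(data_names - meta_names):
                findings.append(Finding(
                    code="metabolite_name_inconsistent", section=block.kind,
                    locus=name,
                    message=f"{name} appears in {block.kind} but not in METABOLITES"))
            for name in sorted(meta_names - data_names):
                findings.append(Finding(
                    code="metabolite_name_inconsistent", section="METABOLITES",
                    locus=name,
                    message=f"{name} appears in METABOLITES but not in {block.kind}"))
    return findings


def is_numeric(value: str,
               missing_tokens: tuple[str, ...] = config.NUMERIC_MISSING_TOKENS,
               ) -> bool:
    if value in missing_tokens:
        return True
    return _NUMERIC_RE.fullmatch(value.strip()) is not None


def check_numeric_data(entry: MWTabEntry,
                       missing_tokens: tuple[str, ...] = config.NUMERIC_MISSING_TOKENS,
                       ) -> list[Finding]:
    """Flag non-numeric cells in MS processed experimental data."""
    findings: list[Finding] = []
    block = entry.sections.get("MS_METABOLITE_DATA")
    if not isinstance(block, DataBlock):
        return findings
    for row in block.rows:
        for sample_id in block.sample_ids:
            value = row.values.get(sample_id, "")
            if not is_numeric(value, missing_tokens):
                findings.append(Finding(
                    code="non_numeric_data", section=block.kind,
                    locus=f"{row.label}/{sample_id}",
                    message=f"non-numeric value {value!r} for metabolite "
                            f"{row.label}, sample {sample_id}"))
    return findings


def check_data_presence(entry: MWTabEntry) -> list[Finding]:
    """Entries must carry processed data, or (MS only) point at a results
    file through an MS_RESULTS_FILE item; the item value may carry trailing
    KEY:VALUE tokens after the leading filename."""
    if _measurement_blocks(entry):
        return []
    if entry.analysis_type == "MS" or "MS" in entry.sections:
        ms = entry.sections.get("MS")
        if isinstance(ms, Section):
            value = ms.items.get("MS_RESULTS_FILE", "")
            if value.split()[:1] and value.split()[0].strip():
                return []
        return [Finding(
            code="missing_data_no_results_file", section="MS",
            locus="MS_RESULTS_FILE",
            message="no measurement data block and no MS_RESULTS_FILE item")]
    return [Finding(
        code="missing_data_no_results_file", section="NMR",
        locus="",
        message="no measurement data block (NMR entries have no results-file "
                "escape hatch)")]


def validate_entry(entry: MWTabEntry, schema: SchemaSpec | None = None,
                   source: str = "") -> ValidationReport:
    """Run every checker and return the union of findings.

    The report is empty iff the entry is valid under ``schema``; the same
    input always yields the same multiset of findings.
    """
    schema = schema or SchemaSpec.default()
    findings: list[Finding] = []
    findings += check_schema(entry, schema)
    findings += check_null_items(entry)
    findings += check_sample_consistency(entry)
    findings += check_metabolite_consistency(entry)
    findings += check_numeric_data(entry)
    findings += check_data_presence(entry)
    return ValidationReport(source=source, findings=findings)
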