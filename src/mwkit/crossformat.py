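"""Cross-format consistency audit.

One analysis is served in two serializations (tab-delimited text and JSON);
this module compares the two parsed renditions and classifies every
divergence: differing section key sets, differing item keys or values
inside a section, mismatched SUBJECT_SAMPLE_FACTORS records, a tabular
block whose rows are present in one serialization but absent in the other,
mismatched units declarations, differing data cells, and sections with the
wrong structural type.

Comparison is string-wise by default — "1.50" versus "1.5" IS a finding,
because the audit's job is detecting serialization divergence, not numeric
disagreement.  The :class:`~mwkit.model.NormalizationPolicy` controls
whitespace and Unicode normalization, which separates encoding artifacts
(composed vs decomposed accents in a units value) from substantive
mismatches.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from typing import Iterable

from .model import (
    DataBlock,
    MWTabEntry,
    NormalizationPolicy,
    Section,
    SubjectSampleFactorList,
)

CONSISTENCY_CODES = (
    "section_keys_mismatch",
    "item_keys_mismatch",
    "item_values_mismatch",
    "ssf_mismatch",
    "data_missing_in_json",
    "data_units_mismatch",
    "data_values_mismatch",
    "wrong_structure",
)

#: Pseudo-section name used for banner-level comparisons.
BANNER_SECTION = "METABOLOMICS WORKBENCH"


@dataclass(frozen=True)
class ConsistencyFinding:
    """One cross-format divergence; ``left``/``right`` hold the verbatim
    (pre-normalization) values so encoding differences stay inspectable."""

    code: str
    section: str
    locus: str
    left: str = ""
    right: str = ""


def _differs(a: str, b: str, policy: NormalizationPolicy) -> bool:
    return policy.apply(a) != policy.apply(b)


def _compare_mappings(section: str, a: dict[str, str], b: dict[str, str],
                      policy: NormalizationPolicy,
                      keys_code: str, values_code: str,
                      ) -> list[ConsistencyFinding]:
    findings = []
    for key in dict.fromkeys(list(a) + list(b)):
        if key not in a or key not in b:
            findings.append(ConsistencyFinding(
                code=keys_code, section=section, locus=key,
                left=a.get(key, ""), right=b.get(key, "")))
        elif _differs(a[key], b[key], policy):
            findings.append(ConsistencyFinding(
                code=values_code, section=section, locus=key,
                left=a[key], right=b[key]))
    return findings


def _compare_ssf(a: SubjectSampleFactorList, b: SubjectSampleFactorList,
                 policy: NormalizationPolicy) -> list[ConsistencyFinding]:
    section = "SUBJECT_SAMPLE_FACTORS"
    if len(a) != len(b):
        return [ConsistencyFinding(
            code="ssf_mismatch", section=section, locus="record count",
            left=str(len(a)), right=str(len(b)))]
    findings = []
    for index, (ra, rb) in enumerate(zip(a, b)):
        same = (not _differs(ra.subject_id, rb.subject_id, policy)
                and not _differs(ra.sample_id, rb.sample_id, policy)
                and list(ra.factors) == list(rb.factors)
                and all(not _differs(ra.factors[k], rb.factors[k], policy)
                        for k in ra.factors)
                and list(ra.additional) == list(rb.additional)
                and all(not _differs(ra.additional[k], rb.additional[k], policy)
                        for k in ra.additional))
        if not same:
            findings.append(ConsistencyFinding(
                code="ssf_mismatch", section=section,
                locus=ra.sample_id or f"record {index}",
                left=repr(ra), right=repr(rb)))
    return findings


def _compare_blocks(name: str, a: DataBlock, b: DataBlock,
                    policy: NormalizationPolicy) -> list[ConsistencyFinding]:
    findings: list[ConsistencyFinding] = []
    if bool(a.rows) != bool(b.rows):
        # one serialization carries the table, the other does not
        findings.append(ConsistencyFinding(
            code="data_missing_in_json", section=name, locus="Data",
            left=f"{len(a.rows)} rows", right=f"{len(b.rows)} rows"))
        return findings
    if _differs(a.units or "", b.units or "", policy):
        findings.append(ConsistencyFinding(
            code="data_units_mismatch", section=name, locus="UNITS",
            left=a.units or "", right=b.units or ""))
    columns_a = a.sample_ids or a.headings
    columns_b = b.sample_ids or b.headings
    if columns_a != columns_b:
        findings.append(ConsistencyFinding(
            code="data_values_mismatch", section=name, locus="column axis",
            left="\t".join(columns_a), right="\t".join(columns_b)))
        return findings
    if len(a.rows) != len(b.rows):
        findings.append(ConsistencyFinding(
            code="data_values_mismatch", section=name, locus="row count",
            left=str(len(a.rows)), right=str(len(b.rows))))
        return findings
    for ra, rb in zip(a.rows, b.rows):
        if _differs(ra.label, rb.label, policy):
            findings.append(ConsistencyFinding(
                code="data_values_mismatch", section=name, locus=ra.label,
                left=ra.label, right=rb.label))
            continue
        for column in columns_a:
            va, vb = ra.values.get(column, ""), rb.values.get(column, "")
            if _differs(va, vb, policy):
                findings.append(ConsistencyFinding(
                    code="data_values_mismatch", section=name,
                    locus=f"{ra.label}/{column}", left=va, right=vb))
    return findings


def compare_entries(text_entry: MWTabEntry, json_entry: MWTabEntry,
                    policy: NormalizationPolicy = NormalizationPolicy.STRIPPED,
                    ) -> list[ConsistencyFinding]:
    """Compare the two renditions of one analysis.

    Returns an empty sequence iff the entries are equal under ``policy``;
    otherwise one finding per divergent section key, item key, item value,
    SUBJECT_SAMPLE_FACTORS record, units value or data cell.  A mismatched
    ANALYSIS_ID is itself a finding (at the banner pseudo-section).
    """
    findings: list[ConsistencyFinding] = []
    banner_a = dict(text_entry.header_ids)
    banner_b = dict(json_entry.header_ids)
    if text_entry.version or json_entry.version:
        banner_a["VERSION"], banner_b["VERSION"] = text_entry.version, json_entry.version
    if text_entry.created_on or json_entry.created_on:
        banner_a["CREATED_ON"] = text_entry.created_on
        banner_b["CREATED_ON"] = json_entry.created_on
    findings += _compare_mappings(BANNER_SECTION, banner_a, banner_b, policy,
                                  "item_keys_mismatch", "item_values_mismatch")
    names_a, names_b = list(text_entry.sections), list(json_entry.sections)
    for name in dict.fromkeys(names_a + names_b):
        if name not in names_a or name not in names_b:
            findings.append(ConsistencyFinding(
                code="section_keys_mismatch", section=name, locus=name,
                left="present" if name in names_a else "absent",
                right="present" if name in names_b else "absent"))
            continue
        ca, cb = text_entry.sections[name], json_entry.sections[name]
        if type(ca) is not type(cb):
            findings.append(ConsistencyFinding(
                code="wrong_structure", section=name, locus=name,
                left=type(ca).__name__, right=type(cb).__name__))
        elif isinstance(ca, Section):
            findings += _compare_mappings(name, ca.items, cb.items, policy,
                                          "item_keys_mismatch", "item_values_mismatch")
        elif isinstance(ca, SubjectSampleFactorList):
            findings += _compare_ssf(ca, cb, policy)
        else:
            findings += _compare_blocks(name, ca, cb, policy)
    return findings


def summarize(findings_per_entry: dict[str, Iterable[ConsistencyFinding]],
              ) -> dict[str, int]:
    """Tally findings over a corpus: each entry is counted once per code,
    regardless of finding multiplicity."""
    tally: dict[str, int] = {code: 0 for code in CONSISTENCY_CODES}
    for findings in findings_per_entry.values():
        for code in {f.code for f in findings}:
            tally[code] = tally.get(code, 0) + 1
    return tally


def findings_to_jsonl(findings: Iterable[ConsistencyFinding]) -> str:
    return "".join(json.dumps(f.__dict__) + "\n" for f in findings)


def findings_to_csv(findings: Iterable[ConsistencyFinding]) -> str:
    out = io.StringIO()
    writer = csv.writer(out)
    writer.writerow(["code", "section", "locus", "left", "right"])
    for f in findings:
        writer.writerow([f.code, f.section, f.locus, f.left, f.right])
    return out.getvalue()


def tally_to_csv(tally: dict[str, int]) -> str:
    out = io.StringIO()
    writer = csv.writer(out)
    writer.writerow(["code", "entries"])
    for code, count in tally.items():
        writer.writerow([code, count])
    return out.getvalue()
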