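"""Standardization of free-text metabolite metadata headings.

Repository depositors name the columns of their METABOLITES tables freely
("PubChem CID", "Inchi_Key", "ri", ...), which hinders cross-study
meta-analysis.  This module matches raw headings against an ordered battery
of case-insensitive regular-expression rules to recover the standardized
field names (hmdb_id, inchi_key, kegg_id, moverz, moverz_quant, other_id,
pubchem_id, retention_index, retention_time), and lints headings that match
but are logically suspect (unit annotations on the dimensionless retention
index; units embedded in retention-time heading names instead of a separate
retention_time_units heading).

The rule battery is data, not code: it ships as a config table
(:data:`mwkit.config.DEFAULT_HEADING_RULES`) so repositories can extend it.
Precedence ranks make the more specific rule win when two match — the
retention_time pattern also matches "retention time index", which belongs
to retention_index.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Any, Iterable

from . import config
from .model import DataBlock, MWTabEntry

#: Sentinel for a heading no rule matches.
NO_MATCH = None

_UNIT_ANNOTATION_RE = re.compile(
    r"\(\s*(min(ute)?s?|sec(ond)?s?|hr?s?|hours?|ms)\s*\)", re.IGNORECASE)


def _normalize_pattern(pattern: str) -> str:
    # The printed rule grammar uses "{,}" (zero-or-more); Python's re treats
    # a bare "{,}" as literal text, so rewrite it to "*" at load time.
    return pattern.replace("{,}", "*")


@dataclass
class HeadingRule:
    """One standardized field name with its ordered match patterns and
    precedence rank (lower rank is tried first)."""

    canonical: str
    patterns: list[str]
    precedence: int = 0
    _compiled: list[re.Pattern] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self._compiled = [re.compile(_normalize_pattern(p)) for p in self.patterns]

    def matches(self, heading: str) -> str | None:
        """Return the first matching pattern string, or None."""
        for raw_pattern, compiled in zip(self.patterns, self._compiled):
            if compiled.search(heading):
                return raw_pattern
        return None


def load_rules(table: Iterable[dict[str, Any]] | None = None) -> list[HeadingRule]:
    """Build the rule battery from a config table (defaults shipped)."""
    table = table if table is not None else config.DEFAULT_HEADING_RULES
    rules = [HeadingRule(canonical=row["canonical"],
                         patterns=list(row["patterns"]),
                         precedence=int(row.get("precedence", 0)))
             for row in table]
    return sorted(rules, key=lambda r: r.precedence)


def standardize_heading(raw: str, rules: list[HeadingRule] | None = None,
                        ) -> str | None:
    """Map a raw heading to its standardized field name, or :data:`NO_MATCH`.

    The heading is whitespace-stripped before matching; the
    highest-precedence rule with a matching pattern wins.  Total and
    deterministic; all patterns are case-insensitive.
    """
    rules = rules if rules is not None else load_rules()
    heading = raw.strip()
    for rule in rules:
        if rule.matches(heading) is not None:
            return rule.canonical
    return NO_MATCH


def audit_headings(entry: MWTabEntry, rules: list[HeadingRule] | None = None,
                   ) -> dict[str, str | None]:
    """One standardization decision per distinct METABOLITES heading.

    Returns an empty mapping when the entry has no METABOLITES block.
    """
    rules = rules if rules is not None else load_rules()
    block = entry.sections.get("METABOLITES")
    if not isinstance(block, DataBlock):
        return {}
    return {heading: standardize_heading(heading, rules)
            for heading in dict.fromkeys(block.headings)}


@dataclass(frozen=True)
class LintFinding:
    """A logically suspect heading: code, message, optional suggestion."""

    code: str
    heading: str
    message: str
    suggestion: str = ""


def lint_heading(raw: str, canonical: str) -> list[LintFinding]:
    """Lint a heading already assigned to a canonical field.

    The retention index is dimensionless (a normalization of retention time
    against two eluted standards), so any unit annotation on it is an
    error.  Units embedded in retention_time headings are legal but hinder
    parsing; a separate retention_time_units heading is suggested.
    """
    findings: list[LintFinding] = []
    unit = _UNIT_ANNOTATION_RE.search(raw)
    if unit is None:
        return findings
    if canonical == "retention_index":
        findings.append(LintFinding(
            code="units_on_dimensionless", heading=raw,
            message=f"retention index is dimensionless but heading {raw!r} "
                    f"carries the unit annotation {unit.group(0)!r}"))
    elif canonical == "retention_time":
        findings.append(LintFinding(
            code="embedded_units", heading=raw,
            message=f"heading {raw!r} embeds units in the field name",
            suggestion="retention_time_units"))
    return findings


def audit_to_csv(entry: MWTabEntry, rules: list[HeadingRule] | None = None) -> str:
    """Export the audit as CSV with columns raw, canonical, matched_pattern."""
    rules = rules if rules is not None else load_rules()
    block = entry.sections.get("METABOLITES")
    out = io.StringIO()
    writer = csv.writer(out)
    writer.writerow(["raw", "canonical", "matched_pattern"])
    if isinstance(block, DataBlock):
        for heading in dict.fromkeys(block.headings):
            stripped = heading.strip()
            for rule in rules:
                pattern = rule.matches(stripped)
                if pattern is not None:
                    writer.writerow([heading, rule.canonical, pattern])
                    break
            else:
                writer.writerow([heading, "", ""])
    return out.getvalue()
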