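"""Ordered, serialization-neutral document model for Metabolomics Workbench entries.

One analysis entry ("mwTab file") is a sequence of named sections: free-text
metadata sections holding key-value items (PROJECT, STUDY, ...), the
SUBJECT_SAMPLE_FACTORS table linking samples to subjects and experimental
factors, and tabular measurement blocks (MS/NMR metabolite data, binned NMR
spectra, the METABOLITES metadata table and its EXTENDED_* subsections).

Both the tab-delimited text reader and the JSON reader populate this model;
every downstream operation (validation, cross-format comparison, extraction)
consumes it.  All values are stored as strings so that serialization
round-trips are lossless; numeric interpretation happens only in the
validator.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterator, Union

#: Item sections and their text-format key prefixes ("PR:INSTITUTE" etc.).
SECTION_PREFIXES: dict[str, str] = {
    "PROJECT": "PR",
    "STUDY": "ST",
    "SUBJECT": "SU",
    "COLLECTION": "CO",
    "TREATMENT": "TR",
    "SAMPLEPREP": "SP",
    "CHROMATOGRAPHY": "CH",
    "ANALYSIS": "AN",
    "MS": "MS",
    "NMR": "NM",
}
ITEM_SECTION_NAMES: tuple[str, ...] = tuple(SECTION_PREFIXES)
PREFIX_TO_SECTION: dict[str, str] = {v: k for k, v in SECTION_PREFIXES.items()}

SSF_SECTION_NAME = "SUBJECT_SAMPLE_FACTORS"

MEASUREMENT_BLOCK_KINDS: tuple[str, ...] = (
    "MS_METABOLITE_DATA",
    "NMR_METABOLITE_DATA",
    "NMR_BINNED_DATA",
)
EXTENDED_BLOCK_KINDS: tuple[str, ...] = (
    "EXTENDED_MS_METABOLITE_DATA",
    "EXTENDED_NMR_METABOLITE_DATA",
)
DATA_BLOCK_KINDS: tuple[str, ...] = (
    MEASUREMENT_BLOCK_KINDS + ("METABOLITES",) + EXTENDED_BLOCK_KINDS
)

#: The canonical section namespace shared by both serializations.  The list is
#: editable config: readers preserve unknown sections verbatim rather than
#: dropping them.
CANONICAL_SECTION_NAMES: tuple[str, ...] = (
    ITEM_SECTION_NAMES + (SSF_SECTION_NAME,) + DATA_BLOCK_KINDS
)

#: Spelling variants mapped onto the canonical (text-format) section names.
SECTION_ALIASES: dict[str, str] = {
    "NM": "NMR",
    "MS_METABOLITES_DATA": "MS_METABOLITE_DATA",
    "NMR_METABOLITES_DATA": "NMR_METABOLITE_DATA",
    "SUBJECT_SAMPLE_FACTOR": "SUBJECT_SAMPLE_FACTORS",
}

HEADER_ID_PATTERNS: dict[str, str] = {
    "STUDY_ID": r"ST\d+",
    "ANALYSIS_ID": r"AN\d+",
    "PROJECT_ID": r"PR\d+",
    "DATATRACK_ID": r"DT\d+",
}

#: Placeholder used in SUBJECT_SAMPLE_FACTORS for a missing subject; stored
#: verbatim, never converted to an empty value.
SUBJECT_PLACEHOLDER = "-"


class _Missing:
    """Absent-section marker returned by :func:`get_section`."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

_WS_RUN = re.compile(r"\s+")


class NormalizationPolicy(enum.Enum):
    """How string values are normalized before comparison.

    RAW compares byte-for-byte; STRIPPED removes leading/trailing whitespace;
    NORMALIZED additionally applies Unicode NFC and collapses internal
    whitespace runs, separating encoding artifacts from substantive
    mismatches.
    """

    RAW = "raw"
    STRIPPED = "stripped"
    NORMALIZED = "normalized"

    def apply(self, value: str) -> str:
        if self is NormalizationPolicy.RAW:
            return value
        if self is NormalizationPolicy.STRIPPED:
            return value.strip()
        return _WS_RUN.sub(" ", unicodedata.normalize("NFC", value.strip()))


@dataclass
class Section:
    """A key-value metadata section (PROJECT, STUDY, ..., MS, NMR).

    ``items`` maps the bare item key (``INSTITUTE``, not ``PR:INSTITUTE``) to
    its string value; insertion order equals file order.  ``known`` is False
    for sections outside the canonical namespace, which are preserved
    verbatim with this provenance flag rather than dropped.
    """

    name: str
    items: dict[str, str] = field(default_factory=dict)
    known: bool = True


@dataclass
class SubjectSampleFactor:
    """One SUBJECT_SAMPLE_FACTORS record.

    ``factors`` holds the experimental factor assignments; ``additional``
    holds the semicolon-separated extra key-value pairs, which is where
    RAW_FILE_NAME and subject/sample lineage metadata live.
    """

    subject_id: str = SUBJECT_PLACEHOLDER
    sample_id: str = ""
    factors: dict[str, str] = field(default_factory=dict)
    additional: dict[str, str] = field(default_factory=dict)


class SubjectSampleFactorList(list):
    """Ordered collection of :class:`SubjectSampleFactor` records."""

    def sample_ids(self) -> list[str]:
        return [record.sample_id for record in self]


@dataclass
class Row:
    """One row of a tabular block: a metabolite (or bin) label plus its
    ordered column values."""

    label: str
    values: dict[str, str] = field(default_factory=dict)


@dataclass
class DataBlock:
    """A tabular block.

    For measurement kinds (MS_METABOLITE_DATA, NMR_METABOLITE_DATA,
    NMR_BINNED_DATA) the columns are ``sample_ids`` and every row carries one
    value per sample.  For METABOLITES the columns are metadata ``headings``
    (hmdb_id, m/z, ...).  For EXTENDED_* kinds the first heading is
    ``sample_id``: each row is simultaneously metabolite-specific (the label)
    and sample-specific (the ``sample_id`` value), carrying per-(metabolite,
    sample) measurements such as retention time.
    """

    kind: str
    units: str | None = None
    sample_ids: list[str] = field(default_factory=list)
    headings: list[str] = field(default_factory=list)
    rows: list[Row] = field(default_factory=list)
    factor_row: list[str] | None = None
    label_header: str = ""

    def metabolite_names(self) -> list[str]:
        return [row.label for row in self.rows]


SectionContent = Union[Section, SubjectSampleFactorList, DataBlock]


@dataclass
class MWTabEntry:
    """In-memory twin of one analysis file in either serialization.

    ``header_ids`` holds the banner identifiers (STUDY_ID, ANALYSIS_ID,
    PROJECT_ID, DATATRACK_ID) in banner order.  ``sections`` preserves file
    order exactly; iteration order equals file order.
    """

    header_ids: dict[str, str] = field(default_factory=dict)
    version: str = ""
    created_on: str = ""
    sections: dict[str, SectionContent] = field(default_factory=dict)
    source_format: str | None = None

    def __post_init__(self) -> None:
        for kind, value in self.header_ids.items():
            pattern = HEADER_ID_PATTERNS.get(kind)
            if pattern and not re.fullmatch(pattern, value):
                raise ValueError(f"malformed {kind} identifier: {value!r}")

    @property
    def analysis_id(self) -> str:
        return self.header_ids.get("ANALYSIS_ID", "")

    @property
    def study_id(self) -> str:
        return self.header_ids.get("STUDY_ID", "")

    @property
    def analysis_type(self) -> str:
        """"MS" or "NMR" as declared in AN:ANALYSIS_TYPE ("" when absent)."""
        analysis = self.sections.get("ANALYSIS")
        if isinstance(analysis, Section):
            return analysis.items.get("ANALYSIS_TYPE", "")
        return ""

    def __iter__(self) -> Iterator[str]:
        return iter(self.sections)


def resolve_section_name(name: str) -> str:
    """Map a (possibly aliased) section name onto the canonical spelling."""
    return SECTION_ALIASES.get(name, name)


def get_section(entry: MWTabEntry, name: str):
    """Return the stored content for ``name``, or :data:`MISSING`.

    ``name`` may be a canonical section name or a recognized alias.  Names
    outside the canonical namespace that are also not present in the entry
    (i.e. not even a preserved unknown section) raise ``KeyError``.
    """
    canonical = resolve_section_name(name)
    if canonical not in CANONICAL_SECTION_NAMES and canonical not in entry.sections:
        raise KeyError(f"unrecognized section name: {name!r}")
    return entry.sections.get(canonical, MISSING)


def _eq(a: str, b: str, policy: NormalizationPolicy) -> bool:
    return policy.apply(a) == policy.apply(b)


def _mapping_equal(a: dict[str, str], b: dict[str, str], policy: NormalizationPolicy) -> bool:
    if list(a) != list(b):
        return False
    return all(_eq(a[k], b[k], policy) for k in a)


def _ssf_equal(a: SubjectSampleFactorList, b: SubjectSampleFactorList,
               policy: NormalizationPolicy) -> bool:
    if len(a) != len(b):
        return False
    for ra, rb in zip(a, b):
        if not _eq(ra.subject_id, rb.subject_id, policy):
            return False
        if not _eq(ra.sample_id, rb.sample_id, policy):
            return False
        if not _mapping_equal(ra.factors, rb.factors, policy):
            return False
        if not _mapping_equal(ra.additional, rb.additional, policy):
            return False
    return True


def _block_equal(a: DataBlock, b: DataBlock, policy: NormalizationPolicy) -> bool:
    if a.kind != b.kind:
        return False
    ua, ub = a.units or "", b.units or ""
    if not _eq(ua, ub, policy):
        return False
    if a.sample_ids != b.sample_ids or a.headings != b.headings:
        return False
    if (a.factor_row or None) != (b.factor_row or None):
        return False
    if len(a.rows) != len(b.rows):
        return False
    for ra, rb in zip(a.rows, b.rows):
        if not _eq(ra.label, rb.label, policy):
            return False
        if not _mapping_equal(ra.values, rb.values, policy):
            return False
    return True


def equal_entries(a: MWTabEntry, b: MWTabEntry,
                  policy: NormalizationPolicy = NormalizationPolicy.RAW) -> bool:
    """True iff the two entries agree on every section, item, record and cell
    under ``policy``.  An equivalence relation for any fixed policy."""
    if not _mapping_equal(a.header_ids, b.header_ids, policy):
        return False
    if not _eq(a.version, b.version, policy) or not _eq(a.created_on, b.created_on, policy):
        return False
    if list(a.sections) != list(b.sections):
        return False
    for name in a.sections:
        ca, cb = a.sections[name], b.sections[name]
        if type(ca) is not type(cb):
            return False
        if isinstance(ca, Section):
            if not _mapping_equal(ca.items, cb.items, policy):
                return False
        elif isinstance(ca, SubjectSampleFactorList):
            if not _ssf_equal(ca, cb, policy):
                return False
        else:
            if not _block_equal(ca, cb, policy):
                return False
    return True
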