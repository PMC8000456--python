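"""Synthetic entry generation and defect injection.

The generator produces structurally valid, schema-complete analysis entries
(MS, targeted NMR or binned NMR) together with a ground-truth manifest of
every planted value, so that parser, validator, cross-format and extraction
behavior can be tested offline with exact expected answers.  Fixtures test
structure, not biology: intensities are plain pseudo-random decimals, and
the planted vocabulary (metabolite names, institutes, factor levels) comes
from small embedded word lists.

``inject_defect`` mutates a clean artifact to plant exactly one defect of a
named class and returns a :class:`DefectRecord` locating it:

* parse classes operate on the text serialization (a removed tab, a
  stripped ``#`` prefix, a broken VERSION line, ...);
* validation classes operate on the entry object (a nulled item, an
  undeclared sample column, ...);
* cross-format classes operate on a (text entry, JSON entry) pair.

Determinism: a single integer seed drives everything; per-file sub-seeds
are derived by stable hashing of (seed, index), so the same spec + seed
always yields byte-identical output.
"""

from __future__ import annotations

import copy
import hashlib
import json
import random
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Union

from .errors import InjectionError
from .fileio import write_json, write_mwtab
from .model import (
    DataBlock,
    MWTabEntry,
    Row,
    Section,
    SubjectSampleFactor,
    SubjectSampleFactorList,
)

PARSE_DEFECT_CLASSES = (
    "ssf_malformed",
    "missing_hash_prefix",
    "version_line",
    "duplicate_item",
    "analysis_type_line",
    "missing_tab",
    "excessive_tabs",
    "missing_banner",
)

VALIDATION_DEFECT_CLASSES = (
    "schema_missing_item",
    "null_item_value",
    "ssf_null_field",
    "sample_id_inconsistent",
    "sample_id_inconsistent_extended",
    "missing_data_no_results_file",
)

CROSSFORMAT_DEFECT_CLASSES = (
    "section_keys_mismatch",
    "item_keys_mismatch",
    "item_values_mismatch",
    "ssf_mismatch",
    "data_missing_in_json",
    "data_units_mismatch",
    "data_values_mismatch",
)

OTHER_DEFECT_CLASSES = ("blank_body",)

_METABOLITES = (
    "glucose", "alanine", "leucine", "citrate", "lactate", "pyruvate",
    "serine", "glycine", "valine", "fumarate", "malate", "succinate",
    "glutamate", "aspartate", "taurine", "creatinine", "ornithine",
    "proline", "threonine", "tyrosine",
)
_LAST_NAMES = ("Smith", "Jones", "Garcia", "Chen", "Patel", "Okafor")
_FIRST_NAMES = ("Alex", "Maria", "Wei", "Priya", "Sam", "Ngozi")
_INSTITUTES = (
    "University of Northfield", "Coastal Research Institute",
    "Lakeside Medical Center", "Highland State University",
)
_SPECIES = ("Homo sapiens", "Mus musculus", "Rattus norvegicus")
_UNITS_MS = ("peak area", "peak height", "normalized intensity")
_UNITS_NMR = ("relative abundance", "micromoles per gram")
_CHROMATOGRAPHY_TYPES = ("Reversed phase", "HILIC", "GC")
_COLUMNS = ("Waters Acquity BEH C18", "Agilent Zorbax SB-Aq", "Restek Rxi-5ms")
_MS_INSTRUMENTS = ("Thermo Q Exactive", "Agilent 6550 QTOF", "Sciex 5500 QTRAP")
_NMR_INSTRUMENTS = ("Bruker Avance III 600", "Varian Inova 500")
_FACTOR_DESIGNS = {"Treatment": ("Control", "Drug"), "Time": ("0h", "24h")}
_METABOLITE_HEADINGS = ("hmdb_id", "pubchem_id", "kegg_id", "m/z", "ri")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic entry.

    ``analysis_type`` is MS, NMR-targeted (named metabolites) or NMR-binned
    (spectral bins).  ``extended`` adds an EXTENDED_*_METABOLITE_DATA
    subsection with per-(metabolite, sample) retention times.
    ``results_file_only`` produces an MS entry whose data live in a results
    file (MS_RESULTS_FILE item) rather than an in-file data block — a valid
    configuration that must produce zero validation findings.
    """

    analysis_type: str = "MS"
    n_samples: int = 6
    n_metabolites: int = 8
    factor_design: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"Treatment": ("Control", "Drug")})
    extended: bool = False
    results_file_only: bool = False
    seed: int = 0
    index: int = 0

    def __post_init__(self) -> None:
        if self.analysis_type not in ("MS", "NMR-targeted", "NMR-binned"):
            raise ValueError(f"unknown analysis type: {self.analysis_type!r}")
        if self.n_samples < 1:
            raise ValueError("a fixture needs at least one sample")
        if self.n_metabolites < 1 and not self.results_file_only:
            raise ValueError("a fixture with a data block needs metabolites")
        if self.results_file_only and self.analysis_type != "MS":
            raise ValueError("results-file-only entries are MS entries "
                             "(no NMR results-file item exists)")


def subseed(seed: int, token: Union[int, str]) -> int:
    """Stable sub-seed below 2**31 derived from (seed, token)."""
    digest = hashlib.sha256(f"{seed}:{token}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _item_section(name: str, items: dict[str, str]) -> Section:
    return Section(name=name, items=items)


def generate_entry(spec: FixtureSpec) -> tuple[MWTabEntry, dict[str, Any]]:
    """Build one schema-complete entry plus its ground-truth manifest.

    The manifest lists every planted value (ids, sample ids, metabolite
    names, item values, metadata headings) and is the oracle for the
    extraction and validation test suites.
    """
    rng = random.Random(subseed(spec.seed, spec.index))
    number = spec.index + 1 + (spec.seed % 1000) * 100
    study_id = f"ST{number:06d}"
    analysis_id = f"AN{number:06d}"
    project_id = f"PR{number:06d}"
    datatrack_id = f"DT{number:06d}"
    is_ms = spec.analysis_type == "MS"
    analysis_type = "MS" if is_ms else "NMR"

    samples = [f"{study_id}_S{i + 1:02d}" for i in range(spec.n_samples)]
    if spec.analysis_type == "NMR-binned":
        names = [f"{3.0 + 0.04 * i:.2f}..{3.04 + 0.04 * i:.2f}"
                 for i in range(spec.n_metabolites)]
    else:
        names = list(rng.sample(_METABOLITES, min(spec.n_metabolites,
                                                  len(_METABOLITES))))
    first = rng.choice(_FIRST_NAMES)
    last = rng.choice(_LAST_NAMES)
    institute = rng.choice(_INSTITUTES)
    species = rng.choice(_SPECIES)
    chromatography = rng.choice(_CHROMATOGRAPHY_TYPES)
    units = rng.choice(_UNITS_MS if is_ms else _UNITS_NMR)
    factor_names = list(spec.factor_design)

    sections: dict[str, object] = {}
    sections["PROJECT"] = _item_section("PROJECT", {
        "PROJECT_TITLE": f"Metabolic profiling study {project_id}",
        "FIRST_NAME": first,
        "LAST_NAME": last,
        "INSTITUTE": institute,
        "DEPARTMENT": "Biochemistry",
    })
    sections["STUDY"] = _item_section("STUDY", {
        "STUDY_TITLE": f"{spec.analysis_type} analysis of {species} samples",
        "FIRST_NAME": first,
        "LAST_NAME": last,
        "INSTITUTE": institute,
        "STUDY_SUMMARY": "Synthetic entry for structural testing",
    })
    sections["SUBJECT"] = _item_section("SUBJECT", {
        "SUBJECT_TYPE": "Animal" if species != "Homo sapiens" else "Human",
        "SUBJECT_SPECIES": species,
    })
    sections["COLLECTION"] = _item_section("COLLECTION", {
        "COLLECTION_SUMMARY": "Samples were collected and snap frozen",
    })
    sections["TREATMENT"] = _item_section("TREATMENT", {
        "TREATMENT_SUMMARY": "Subjects randomized across factor levels",
    })
    sections["SAMPLEPREP"] = _item_section("SAMPLEPREP", {
        "SAMPLEPREP_SUMMARY": "Metabolites extracted in cold methanol",
        "SAMPLEPREP_PROTOCOL_FILENAME": f"{study_id}_prep_protocol.pdf",
    })

    ssf = SubjectSampleFactorList()
    for i, sample in enumerate(samples):
        factors = {name: spec.factor_design[name][i % len(spec.factor_design[name])]
                   for name in factor_names}
        ssf.append(SubjectSampleFactor(
            subject_id=f"SU{i + 1:04d}",
            sample_id=sample,
            factors=factors,
            additional={"RAW_FILE_NAME": f"{sample}.mzML" if is_ms else f"{sample}.fid",
                        "BATCH": str(1 + i % 2)},
        ))
    sections["SUBJECT_SAMPLE_FACTORS"] = ssf

    if is_ms:
        sections["CHROMATOGRAPHY"] = _item_section("CHROMATOGRAPHY", {
            "CHROMATOGRAPHY_TYPE": chromatography,
            "COLUMN_NAME": rng.choice(_COLUMNS),
            "INSTRUMENT_NAME": "Thermo Vanquish",
        })
    sections["ANALYSIS"] = _item_section("ANALYSIS", {
        "ANALYSIS_TYPE": analysis_type,
    })
    if is_ms:
        ms_items = {
            "INSTRUMENT_NAME": rng.choice(_MS_INSTRUMENTS),
            "INSTRUMENT_TYPE": "Orbitrap",
            "MS_TYPE": "ESI",
            "ION_MODE": rng.choice(("POSITIVE", "NEGATIVE")),
        }
        if spec.results_file_only or rng.random() < 0.3:
            ms_items["MS_RESULTS_FILE"] = (
                f"{study_id}_{analysis_id}_results.txt UNITS:{units.replace(' ', '_')}")
        sections["MS"] = _item_section("MS", ms_items)
    else:
        sections["NMR"] = _item_section("NMR", {
            "INSTRUMENT_NAME": rng.choice(_NMR_INSTRUMENTS),
            "INSTRUMENT_TYPE": "FT-NMR",
            "SPECTROMETER_FREQUENCY": "600 MHz",
        })

    data_kind = {"MS": "MS_METABOLITE_DATA",
                 "NMR-targeted": "NMR_METABOLITE_DATA",
                 "NMR-binned": "NMR_BINNED_DATA"}[spec.analysis_type]
    headings: list[str] = []
    if not spec.results_file_only:
        block = DataBlock(kind=data_kind, units=units, sample_ids=list(samples),
                          label_header="Samples")
        for name in names:
            block.rows.append(Row(
                label=name,
                values={s: f"{rng.uniform(1e3, 5e5):.1f}" for s in samples}))
        sections[data_kind] = block

        if spec.analysis_type != "NMR-binned":
            headings = list(rng.sample(_METABOLITE_HEADINGS, 3))
            meta = DataBlock(kind="METABOLITES", headings=headings,
                             label_header="metabolite_name")
            for name in names:
                meta.rows.append(Row(label=name, values={
                    h: _metadata_value(h, name, rng) for h in headings}))
            sections["METABOLITES"] = meta

        if spec.extended:
            ext_kind = ("EXTENDED_MS_METABOLITE_DATA" if is_ms
                        else "EXTENDED_NMR_METABOLITE_DATA")
            ext = DataBlock(kind=ext_kind,
                            headings=["sample_id", "retention_time"],
                            label_header="metabolite_name")
            for name in names:
                for sample in samples:
                    ext.rows.append(Row(label=name, values={
                        "sample_id": sample,
                        "retention_time": f"{rng.uniform(0.5, 14.0):.2f}",
                    }))
            sections[ext_kind] = ext

    entry = MWTabEntry(
        header_ids={"STUDY_ID": study_id, "ANALYSIS_ID": analysis_id,
                    "PROJECT_ID": project_id, "DATATRACK_ID": datatrack_id},
        version="1",
        created_on="2020-11-19",
        sections=sections,
        source_format=None,
    )
    manifest = {
        "spec": {
            "analysis_type": spec.analysis_type,
            "n_samples": spec.n_samples,
            "n_metabolites": spec.n_metabolites,
            "extended": spec.extended,
            "results_file_only": spec.results_file_only,
            "seed": spec.seed,
            "index": spec.index,
        },
        "analysis_id": analysis_id,
        "study_id": study_id,
        "sample_ids": samples,
        "metabolites": [] if spec.results_file_only else names,
        "units": None if spec.results_file_only else units,
        "headings": headings,
        "items": {
            "PR:LAST_NAME": last,
            "PR:FIRST_NAME": first,
            "PR:INSTITUTE": institute,
            "CH:CHROMATOGRAPHY_TYPE": chromatography if is_ms else None,
            "SU:SUBJECT_SPECIES": species,
        },
    }
    return entry, manifest


def _metadata_value(heading: str, name: str, rng: random.Random) -> str:
    stable = int(hashlib.sha256(name.encode()).hexdigest()[:6], 16)
    if heading == "hmdb_id":
        return f"HMDB{stable % 100000:07d}"
    if heading == "pubchem_id":
        return str(stable % 90000 + 100)
    if heading == "kegg_id":
        return f"C{stable % 10000:05d}"
    if heading == "m/z":
        return f"{rng.uniform(70, 900):.4f}"
    if heading == "ri":
        return f"{rng.uniform(800, 3000):.0f}"
    return "unknown"


@dataclass
class DefectRecord:
    """Where one injected defect lives: class, section/locus, and for text
    mutations the 1-based line number."""

    defect_class: str
    locus: str = ""
    section: str = ""
    line_number: int = 0
    detail: str = ""


Artifact = Union[str, MWTabEntry, tuple]


def inject_defect(artifact: Artifact, defect_class: str, seed: int = 0,
                  ) -> tuple[Artifact, DefectRecord]:
    """Introduce exactly one defect of ``defect_class`` into ``artifact``.

    Text classes expect the mwTab text serialization; validation classes
    expect an :class:`MWTabEntry`; cross-format classes expect a
    (text_entry, json_entry) pair.  ``InjectionError`` is raised when the
    class does not apply to the artifact.
    """
    if defect_class in PARSE_DEFECT_CLASSES or defect_class in OTHER_DEFECT_CLASSES:
        if not isinstance(artifact, str):
            raise InjectionError(f"{defect_class} applies to text serializations")
        return _inject_text_defect(artifact, defect_class, seed)
    if defect_class in VALIDATION_DEFECT_CLASSES:
        if not isinstance(artifact, MWTabEntry):
            raise InjectionError(f"{defect_class} applies to parsed entries")
        return _inject_validation_defect(artifact, defect_class, seed)
    if defect_class in CROSSFORMAT_DEFECT_CLASSES:
        if not (isinstance(artifact, tuple) and len(artifact) == 2):
            raise InjectionError(f"{defect_class} applies to (text, json) entry pairs")
        return _inject_crossformat_defect(artifact, defect_class, seed)
    raise InjectionError(f"unknown defect class: {defect_class!r}")


def _line_index(lines: list[str], predicate, description: str) -> int:
    for i, line in enumerate(lines):
        if predicate(line):
            return i
    raise InjectionError(f"no target line for {description}")


def _inject_text_defect(text: str, defect_class: str, seed: int,
                        ) -> tuple[str, DefectRecord]:
    rng = random.Random(subseed(seed, defect_class))
    lines = text.split("\n")
    if defect_class == "blank_body":
        return "", DefectRecord(defect_class, detail="file emptied")
    if defect_class == "missing_banner":
        if not lines or not lines[0].startswith("#METABOLOMICS WORKBENCH"):
            raise InjectionError("no banner to remove")
        return "\n".join(lines[1:]), DefectRecord(
            defect_class, line_number=1, detail="banner line removed")
    if defect_class == "excessive_tabs":
        idx = _line_index(lines, lambda l: l.startswith("#METABOLOMICS WORKBENCH"),
                          "banner")
        tabs = "\t" * rng.randint(15, 45)
        lines[idx] = lines[idx].replace("#METABOLOMICS WORKBENCH",
                                        "#METABOLOMICS WORKBENCH" + tabs, 1)
        return "\n".join(lines), DefectRecord(
            defect_class, line_number=idx + 1, detail="tab run inserted in banner")
    if defect_class == "version_line":
        idx = _line_index(lines, lambda l: l.startswith("VERSION\t"), "VERSION line")
        lines[idx] = lines[idx].replace("\t", " ", 1)
        return "\n".join(lines), DefectRecord(
            defect_class, line_number=idx + 1, detail="tab replaced by space")
    if defect_class == "missing_tab":
        idx = _line_index(
            lines, lambda l: l.startswith("SP:SAMPLEPREP_PROTOCOL_FILENAME\t"),
            "SP:SAMPLEPREP_PROTOCOL_FILENAME line")
        lines[idx] = lines[idx].replace("\t", " ", 1)
        return "\n".join(lines), DefectRecord(
            defect_class, line_number=idx + 1,
            section="SAMPLEPREP", locus="SAMPLEPREP_PROTOCOL_FILENAME")
    if defect_class == "duplicate_item":
        idx = _line_index(lines, lambda l: l.startswith("PR:INSTITUTE\t"),
                          "PR:INSTITUTE line")
        lines.insert(idx + 1, lines[idx])
        return "\n".join(lines), DefectRecord(
            defect_class, line_number=idx + 2,
            section="PROJECT", locus="INSTITUTE")
    if defect_class == "analysis_type_line":
        idx = _line_index(lines, lambda l: l.startswith("AN:ANALYSIS_TYPE\t"),
                          "AN:ANALYSIS_TYPE line")
        lines[idx] = "AN:ANALYSIS_TYPE\t" + rng.choice(("LC-MS?", "UNKNOWN", ""))
        return "\n".join(lines), DefectRecord(
            defect_class, line_number=idx + 1,
            section="ANALYSIS", locus="ANALYSIS_TYPE")
    if defect_class == "missing_hash_prefix":
        idx = _line_index(
            lines,
            lambda l: l in ("#MS_METABOLITE_DATA", "#NMR_METABOLITE_DATA",
                            "#NMR_BINNED_DATA"),
            "data-block section header")
        lines[idx] = lines[idx][1:]
        return "\n".join(lines), DefectRecord(
            defect_class, line_number=idx + 1, locus=lines[idx])
    if defect_class == "ssf_malformed":
        candidates = [i for i, l in enumerate(lines)
                      if l.startswith("SUBJECT_SAMPLE_FACTORS\t")]
        if not candidates:
            raise InjectionError("no SUBJECT_SAMPLE_FACTORS records")
        idx = rng.choice(candidates)
        head, _, tail = lines[idx].rpartition("\t")
        lines[idx] = head + " " + tail
        return "\n".join(lines), DefectRecord(
            defect_class, line_number=idx + 1, section="SUBJECT_SAMPLE_FACTORS")
    raise InjectionError(f"unhandled text defect class: {defect_class!r}")


def _inject_validation_defect(entry: MWTabEntry, defect_class: str, seed: int,
                              ) -> tuple[MWTabEntry, DefectRecord]:
    rng = random.Random(subseed(seed, defect_class))
    mutated = copy.deepcopy(entry)
    sections = mutated.sections
    if defect_class == "schema_missing_item":
        candidates = [("COLLECTION", "COLLECTION_SUMMARY"),
                      ("TREATMENT", "TREATMENT_SUMMARY"),
                      ("SAMPLEPREP", "SAMPLEPREP_SUMMARY")]
        section_name, key = rng.choice(candidates)
        section = sections.get(section_name)
        if not isinstance(section, Section) or key not in section.items:
            raise InjectionError(f"no {section_name}:{key} item to remove")
        del section.items[key]
        return mutated, DefectRecord(defect_class, locus=key, section=section_name)
    if defect_class == "null_item_value":
        section = sections.get("PROJECT")
        if not isinstance(section, Section) or "DEPARTMENT" not in section.items:
            raise InjectionError("no optional PROJECT item to null out")
        section.items["DEPARTMENT"] = rng.choice(("", "NA", "N/A", "-"))
        return mutated, DefectRecord(defect_class, locus="DEPARTMENT",
                                     section="PROJECT")
    if defect_class == "ssf_null_field":
        ssf = sections.get("SUBJECT_SAMPLE_FACTORS")
        if not isinstance(ssf, SubjectSampleFactorList) or not ssf:
            raise InjectionError("no SUBJECT_SAMPLE_FACTORS records")
        record = rng.choice(list(ssf))
        if not record.factors:
            raise InjectionError("record has no factors to blank")
        factor = rng.choice(list(record.factors))
        record.factors[factor] = ""
        return mutated, DefectRecord(defect_class, locus=record.sample_id,
                                     section="SUBJECT_SAMPLE_FACTORS",
                                     detail=f"factor {factor} blanked")
    if defect_class == "sample_id_inconsistent":
        blocks = [c for c in sections.values()
                  if isinstance(c, DataBlock) and c.sample_ids]
        if not blocks:
            raise InjectionError("no measurement block to extend")
        block = blocks[0]
        ghost = f"SX{rng.randint(90, 99)}"
        block.sample_ids.append(ghost)
        for row in block.rows:
            row.values[ghost] = f"{rng.uniform(1e3, 5e5):.1f}"
        return mutated, DefectRecord(defect_class, locus=ghost, section=block.kind)
    if defect_class == "sample_id_inconsistent_extended":
        blocks = [c for c in sections.values()
                  if isinstance(c, DataBlock) and c.kind.startswith("EXTENDED_")]
        if not blocks:
            raise InjectionError("entry has no EXTENDED_* block")
        block = blocks[0]
        ghost = f"SX{rng.randint(90, 99)}"
        label = block.rows[0].label if block.rows else "glucose"
        block.rows.append(Row(label=label, values={
            "sample_id": ghost,
            **{h: f"{rng.uniform(0.5, 14.0):.2f}"
               for h in block.headings if h != "sample_id"},
        }))
        return mutated, DefectRecord(defect_class, locus=ghost, section=block.kind)
    if defect_class == "missing_data_no_results_file":
        data_names = [n for n, c in sections.items() if isinstance(c, DataBlock)]
        if not data_names:
            raise InjectionError("entry already lacks data blocks")
        for name in data_names:
            del sections[name]
        ms = sections.get("MS")
        if isinstance(ms, Section):
            ms.items.pop("MS_RESULTS_FILE", None)
        return mutated, DefectRecord(defect_class, locus="MS_RESULTS_FILE",
                                     section="MS")
    raise InjectionError(f"unhandled validation defect class: {defect_class!r}")


def _inject_crossformat_defect(pair: tuple, defect_class: str, seed: int,
                               ) -> tuple[tuple, DefectRecord]:
    rng = random.Random(subseed(seed, defect_class))
    text_entry, json_entry = pair
    text_entry = copy.deepcopy(text_entry)
    json_entry = copy.deepcopy(json_entry)
    sections = json_entry.sections
    if defect_class == "section_keys_mismatch":
        name = "TREATMENT" if "TREATMENT" in sections else next(iter(sections))
        del sections[name]
        return (text_entry, json_entry), DefectRecord(
            defect_class, locus=name, section=name)
    if defect_class == "item_keys_mismatch":
        section = text_entry.sections.get("STUDY")
        if not isinstance(section, Section):
            raise InjectionError("no STUDY section")
        section.items["SUBMIT_DATE"] = "2020-11-19"
        return (text_entry, json_entry), DefectRecord(
            defect_class, locus="SUBMIT_DATE", section="STUDY")
    if defect_class == "item_values_mismatch":
        section = sections.get("PROJECT")
        if not isinstance(section, Section) or not section.items:
            raise InjectionError("no PROJECT items")
        key = rng.choice(list(section.items))
        section.items[key] = section.items[key] + " (revised)"
        return (text_entry, json_entry), DefectRecord(
            defect_class, locus=key, section="PROJECT")
    if defect_class == "ssf_mismatch":
        ssf = sections.get("SUBJECT_SAMPLE_FACTORS")
        if not isinstance(ssf, SubjectSampleFactorList) or not ssf:
            raise InjectionError("no SUBJECT_SAMPLE_FACTORS records")
        record = rng.choice(list(ssf))
        if not record.factors:
            raise InjectionError("record has no factors")
        factor = rng.choice(list(record.factors))
        record.factors[factor] = record.factors[factor] + "-b"
        return (text_entry, json_entry), DefectRecord(
            defect_class, locus=record.sample_id,
            section="SUBJECT_SAMPLE_FACTORS")
    blocks = {n: c for n, c in sections.items()
              if isinstance(c, DataBlock) and c.sample_ids}
    if not blocks:
        raise InjectionError("no measurement block in pair")
    name, block = next(iter(blocks.items()))
    if defect_class == "data_missing_in_json":
        block.rows = []
        block.sample_ids = []
        return (text_entry, json_entry), DefectRecord(
            defect_class, locus="Data", section=name)
    if defect_class == "data_units_mismatch":
        # plant an NFC/NFD pair: composed accent on the text side, decomposed
        # on the JSON side — a pure encoding artifact, not a content change
        composed = "intensité (a.u.)"
        text_block = text_entry.sections[name]
        text_block.units = composed
        block.units = unicodedata.normalize("NFD", composed)
        return (text_entry, json_entry), DefectRecord(
            defect_class, locus="UNITS", section=name)
    if defect_class == "data_values_mismatch":
        row = rng.choice(block.rows)
        sample = rng.choice(block.sample_ids)
        row.values[sample] = "999999.9"
        return (text_entry, json_entry), DefectRecord(
            defect_class, locus=f"{row.label}/{sample}", section=name)
    raise InjectionError(f"unhandled cross-format defect class: {defect_class!r}")


def generate_corpus(n: int, defect_mix: dict[str, float] | None = None,
                    seed: int = 0, destination: str | Path | None = None,
                    spec_kwargs: dict[str, Any] | None = None,
                    ) -> dict[str, Any]:
    """Generate ``n`` paired text/JSON fixtures with an optional defect mix.

    ``defect_mix`` maps defect class to the fraction of fixtures carrying
    it (fractions must sum to <= 1); allocation is deterministic from the
    seed.  Returns the corpus manifest; when ``destination`` is given, the
    paired ``.txt``/``.json`` files and ``manifest.json`` are written there.
    """
    defect_mix = defect_mix or {}
    total = sum(defect_mix.values())
    if total > 1 + 1e-9:
        raise ValueError("defect fractions must sum to at most 1")
    assignments: list[str | None] = []
    for defect_class, fraction in defect_mix.items():
        assignments += [defect_class] * round(fraction * n)
    assignments += [None] * (n - len(assignments))
    random.Random(subseed(seed, 10**6)).shuffle(assignments)

    manifest: dict[str, Any] = {"seed": seed, "n": n, "files": []}
    records = []
    for index, defect_class in enumerate(assignments):
        spec = FixtureSpec(seed=seed, index=index, **(spec_kwargs or {}))
        if defect_class == "sample_id_inconsistent_extended":
            spec.extended = True
        entry, entry_manifest = generate_entry(spec)
        text = write_mwtab(entry)
        json_text = write_json(entry)
        defect_record = None
        if defect_class in PARSE_DEFECT_CLASSES or defect_class in OTHER_DEFECT_CLASSES:
            text, defect_record = inject_defect(text, defect_class, seed + index)
        elif defect_class in VALIDATION_DEFECT_CLASSES:
            mutated, defect_record = inject_defect(entry, defect_class, seed + index)
            text = write_mwtab(mutated)
            json_text = write_json(mutated)
        elif defect_class in CROSSFORMAT_DEFECT_CLASSES:
            from .fileio import parse_json
            pair = (entry, parse_json(json_text))
            (text_entry, json_mutated), defect_record = inject_defect(
                pair, defect_class, seed + index)
            text = write_mwtab(text_entry)
            json_text = write_json(json_mutated)
        file_record = {
            "index": index,
            "analysis_id": entry_manifest["analysis_id"],
            "defect": None if defect_record is None else {
                "class": defect_record.defect_class,
                "locus": defect_record.locus,
                "section": defect_record.section,
                "line_number": defect_record.line_number,
            },
            "ground_truth": entry_manifest,
        }
        manifest["files"].append(file_record)
        records.append((entry_manifest["analysis_id"], text, json_text))

    if destination is not None:
        destination = Path(destination)
        destination.mkdir(parents=True, exist_ok=True)
        for analysis_id, text, json_text in records:
            (destination / f"{analysis_id}.txt").write_text(text, encoding="utf-8")
            (destination / f"{analysis_id}.json").write_text(json_text, encoding="utf-8")
        (destination / "manifest.json").write_text(
            json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
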