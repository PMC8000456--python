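# mwkit

A toolkit for working with **Metabolomics Workbench analysis entries**: the
tab-delimited `mwTab` text format and its JSON mirror. It is aimed at
depositors who want to check a file before submission, curators auditing a
repository for quality problems, and analysts assembling multi-study
meta-analyses who need consistent, machine-readable metadata.

One analysis entry describes a single MS or NMR experiment as an ordered
sequence of sections: key-value metadata blocks (`PROJECT`, `STUDY`,
`SUBJECT`, `COLLECTION`, `TREATMENT`, `SAMPLEPREP`, `CHROMATOGRAPHY`,
`ANALYSIS`, `MS`/`NMR`), the `SUBJECT_SAMPLE_FACTORS` table linking each
sample to its subject, experimental factors and raw-file names, and tabular
measurement blocks (`MS_METABOLITE_DATA`, `NMR_METABOLITE_DATA`,
`NMR_BINNED_DATA`, the `METABOLITES` metadata table, and
`EXTENDED_MS(NMR)_METABOLITE_DATA` subsections holding values that are
simultaneously metabolite- and sample-specific).

The package provides:

- **Parsing and writing** of both serializations with lossless round trips
  (`mwkit.parse_mwtab`, `parse_json`, `write_mwtab`, `write_json`). Parse
  failures carry a machine-readable defect code and line number (malformed
  `SUBJECT_SAMPLE_FACTORS` records, section headers missing their `#`
  prefix, broken `VERSION` lines, duplicated items, bad `ANALYSIS_TYPE`
  lines, missing tab delimiters, tab runs in the banner, missing banner).
- **Validation** (`mwkit.validate_entry`): schema conformance, null item
  values, sample-ID consistency between `SUBJECT_SAMPLE_FACTORS` and the
  data blocks, metabolite-name consistency between the data block and
  `METABOLITES`, numeric-data checks, and the data-presence rule (an MS
  entry without in-file data must name an `MS_RESULTS_FILE`).
- **Cross-format auditing** (`mwkit.compare_entries`): classify every
  divergence between the text and JSON renditions of one analysis, with a
  normalization policy that separates Unicode-encoding artifacts from real
  mismatches.
- **Heading standardization** (`mwkit.standardize_heading`): map free-text
  `METABOLITES` column headings ("PubChem CID", "Inchi_Key", "ri", ...) to
  standardized field names via a configurable regular-expression battery,
  plus lint rules (a unit annotation on the dimensionless retention index
  is an error).
- **REST URL construction and retrieval** (`mwkit.build_url`,
  `download_all`) with an injectable transport so everything is testable
  offline.
- **Corpus search** (`mwkit.extract_metadata`, `extract_metabolites`).
- **Synthetic fixtures** (`mwkit.generate_corpus`): valid entries with
  ground-truth manifests, plus injection of 21 cataloged defect classes.

## Worked example

```python
from mwkit import (FixtureSpec, generate_entry, write_mwtab, parse_mwtab,
                   validate_entry, inject_defect)

entry, manifest = generate_entry(FixtureSpec(analysis_type="MS", seed=11))
text = write_mwtab(entry)
print(text.splitlines()[0])
print(len(validate_entry(entry)))

broken, record = inject_defect(entry, "sample_id_inconsistent", seed=11)
report = validate_entry(broken)
for finding in report.findings:
    print(finding.code, finding.section, finding.locus)
```

prints

```
#METABOLOMICS WORKBENCH STUDY_ID:ST001101 ANALYSIS_ID:AN001101 PROJECT_ID:PR001101 DATATRACK_ID:DT001101
0
sample_id_inconsistent MS_METABOLITE_DATA SX93
```

The first line is the entry's banner with its identifiers; the `0` says the
clean synthetic entry produces an empty validation report; after planting
an undeclared sample column `SX93` in the measurement table, the validator
reports exactly that sample as inconsistent with `SUBJECT_SAMPLE_FACTORS`.

From the shell, the same machinery looks like:

```bash
mwkit fixtures generate corpus/ --n 20 --seed 7 --defect ssf_malformed=0.2
mwkit validate corpus/AN000701.txt
mwkit audit-pair corpus/AN000701.txt corpus/AN000701.json
mwkit extract metadata corpus/ - LAST_NAME --to-format=csv
mwkit download AN000001            # live REST retrieval
```

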