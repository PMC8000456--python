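# Methods

## The document model

An analysis entry is modeled as an ordered mapping of section name to
section content (`MWTabEntry.sections`), preceded by the banner identifiers
(`STUDY_ID`, `ANALYSIS_ID`, `PROJECT_ID`, `DATATRACK_ID`), a `VERSION` and a
`CREATED_ON` value. Three content types cover every section: key-value
`Section`s, the `SubjectSampleFactorList` of per-sample records, and
tabular `DataBlock`s. The model is serialization-neutral: the text reader
and the JSON reader populate the same structures, and every downstream
operation (validation, cross-format comparison, extraction) consumes the
model, never the raw bytes.

Two deliberate commitments shape everything else:

- **All values are strings.** Numeric interpretation happens only in the
  validator. This makes `parse(write(entry)) == entry` an exact identity
  and keeps the cross-format audit honest: `"1.50"` versus `"1.5"` is a
  real serialization divergence, not noise to be coerced away.
- **Order is data.** Section order, item order, record order and row order
  are preserved exactly as read; equality and the audit compare ordered
  structures. Unknown sections are kept verbatim with a provenance flag
  (`Section.known = False`) rather than dropped — a parser must not lose
  what it cannot classify.

Canonical section names use the text-format spellings; a small alias table
maps variants (`NM` → `NMR`, `MS_METABOLITES_DATA` → `MS_METABOLITE_DATA`)
onto them so both serializations share one namespace. The canonical list
ships as editable data in `mwkit.model`, not hard-coded behavior.

## Text dialect

The tokenizer classifies every input line into one of eleven kinds and is
lossless: joining the raw lines reproduces the input byte-for-byte, and
malformed lines are classified rather than discarded. Dialect rules:

- item lines are `KEY<tab…>VALUE`; one **or more** tabs separate key and
  value, trailing spaces are stripped from the key but never from the
  value (padded layouts occur in the wild; values must stay verbatim);
- tabular blocks are delimited by `NAME_START` / `NAME_END` lines, with an
  optional `NAME:UNITS<tab>value` line; units get their own line kind
  because mismatched units are a distinct audit category;
- banner identifier tokens are space-separated `KEY:VALUE` pairs; tab runs
  inside the banner are collapsed for recovery and recorded as a defect
  (the strict parser rejects the file, the tokenizer still yields the
  identifiers);
- `EXTENDED_*_METABOLITE_DATA` blocks are written nested inside the
  `#METABOLITES` section, mirroring their role as a subsection, but are
  stored as their own entry in the section mapping;
- `#END` and trailing blank lines are tolerated and preserved.

### Parse-defect classes

The paperwork of a failed parse is a machine-readable code plus a 1-based
line number. The classes and the concrete rules that trigger them:

| code | trigger |
|---|---|
| `ssf_malformed` | a `SUBJECT_SAMPLE_FACTORS` record with the wrong tab-separated field count |
| `missing_hash_prefix` | a bare canonical section name where a `#` header is expected |
| `version_line` | a header-region `VERSION` line with no tab-separated value |
| `duplicate_item` | the same item key twice within one section |
| `analysis_type_line` | `AN:ANALYSIS_TYPE` value other than `MS`/`NMR` |
| `missing_tab` | an item key followed by a space instead of a tab |
| `excessive_tabs` | tab characters inside the banner line |
| `missing_banner` | the first non-blank line is not the banner |

plus `empty_file` (zero-byte or whitespace-only bodies), and for JSON:
`json_syntax`, `missing_banner`, `wrong_structure` (e.g. a section encoded
as a list where an object is expected). These failure *sites* are taken
from observed repository defects; the exact machine rules above are this
package's own choices and are what the fixture injector produces.

Duplicate items fail the parse by default; a lenient mode is deliberately
not offered at the parser level — the validator is the place for tolerant
auditing, the parser's contract is all-or-nothing.

## Validation

`validate_entry` runs five independent checkers and returns their union —
it never stops at the first finding, so one pass yields the complete defect
census for a file:

1. **Sample consistency** — no blank sample ids or factor values; every
   sample id used in a measurement block or an `EXTENDED_*` block must be
   declared in `SUBJECT_SAMPLE_FACTORS`. The declared set may be a strict
   superset (samples without processed data are legitimate), so the check
   is subset-direction only.
2. **Metabolite consistency** — no blank metabolite names; the name sets of
   the measurement block and the `METABOLITES` table must coincide (both
   directions flagged, one finding per name). Binned NMR entries are
   exempt: spectral bins have no metadata table to cross-check.
3. **Numeric data** — every `MS_METABOLITE_DATA` cell must be a decimal
   numeral (optional sign, optional scientific notation) or an allowed
   missing token. The missing-token set defaults to the empty string only
   — the strictest defensible reading; `NA`-style tokens in measurement
   cells are flagged. Both token sets are config.
4. **Schema** — required sections (plus `CHROMATOGRAPHY`/`MS` for MS
   entries, `NMR` for NMR entries) and required items per section, shipped
   as a versioned config document. A required item that is present but
   null-valued is flagged by this checker *and* by the null-value checker:
   one defect, two distinct codes, because the two checkers answer
   different questions (is the schema satisfied? / is the value usable?).
5. **Data presence** — an entry with no measurement block must, for MS,
   carry an `MS_RESULTS_FILE` item (the value may carry trailing
   `KEY:VALUE` tokens after the leading filename, which is the accepted
   expanded form); NMR has no results-file escape hatch, so a data-less
   NMR entry is always flagged.

Null tokens default to `"", "NA", "N/A", "-"`. The `-` placeholder in the
*subject* column of `SUBJECT_SAMPLE_FACTORS` is not a null: it is stored
verbatim and is legal there.

## Cross-format audit

`compare_entries` walks both renditions in parallel and emits one coded
finding per divergent section key, item key, item value, subject-sample
record, units declaration or data cell. Normalization policies:

- `raw` — byte-wise;
- `stripped` (default for audits) — leading/trailing whitespace removed;
- `normalized` — stripped + Unicode NFC + internal whitespace collapsed.

The `normalized` level exists to separate encoding artifacts from
substantive mismatches: a units value stored composed in one serialization
and decomposed in the other is the same glyph sequence, and its finding
disappears under `normalized` while surviving `stripped`. Data-cell
comparison is string-wise by design (see model commitments); corpus
tallies count each entry once per finding code regardless of multiplicity.

## Heading standardization

The rule battery is data: an ordered list of (canonical name, patterns,
precedence rank). Patterns are case-insensitive; the written form uses the
`{,}` zero-or-more quantifier, normalized to `*` at load time since
Python's `re` treats a bare `{,}` literally. Matching is `re.search` on the
whitespace-stripped heading; the lowest precedence rank wins, which makes
the specific rule beat the broad one: `retention_index` outranks
`retention_time` (whose pattern also matches "retention time index"), and
`moverz_quant` outranks `moverz`. One shipped extension beyond the surveyed
patterns: `moverz` also matches the anchored literal `(?i)(moverz)$`, so
every canonical name used verbatim as a heading maps to itself.

Lint rules ride on top of standardization: a unit annotation such as
`(min)` on a `retention_index` heading is an error (the retention index is
dimensionless — it normalizes a compound's retention time against two
eluted standards), while units embedded in a `retention_time` heading are
legal but fragile, and a separate `retention_time_units` heading is
suggested.

## REST URLs

A request is context + input specification (item, value) + output
specification (item, format), rendered as path segments under
`https://www.metabolomicsworkbench.org/rest/`. The validity table of
(context, input item, output item) triples ships as config seeded from the
demonstrated combinations (`study` × {`analysis_id`, `study_id`} ×
`mwtab`; `compound` × `formula` × `all`); unknown triples fail closed,
with `strict=False` as the explicit override. Rendering and re-parsing are
mutually inverse on valid inputs. All retrieval goes through a transport
contract (`fetch(url) -> (status, body)`); the HTTP transport applies a
0.5 s courteous delay and bounded exponential-backoff retry, and the mock
transport makes every network path testable offline. Bulk download records
per-ID outcomes (`ok` / `blank_body` / `retrieval_error`) in a manifest
and is idempotent under `--resume`.

## Synthetic fixtures

The generator emulates the *structure* of repository entries, not their
biology: schema-complete metadata sections, a subject/sample/factor table
with raw-file names, measurement tables with plain pseudo-random decimal
intensities, a `METABOLITES` table with identifier-shaped values, and
optionally `EXTENDED_*` rows keyed by (metabolite, sample). Defaults —
6 samples, 8 metabolites, one two-level factor — are the size of a small
real study and keep every test corpus fast. What it does **not** emulate:
realistic intensity distributions, correlated factors, free-text prose
quirks, legacy-era layouts, or the deposit-time heading chaos beyond the
five planted heading spellings. Passing tests therefore demonstrate
structural correctness of parsing/validation/auditing, not robustness to
every historical file in the wild.

Defect injection mutates one clean artifact per call and returns a record
locating the defect, which is the oracle the test suites check against.
Injections are designed to be *surgical*: exactly one checker fires, with
no collateral findings. Two places required care: removing the data block
for the data-presence defect also removes the `METABOLITES` table (else
the metabolite-consistency checker would fire too), and the null-value
defect targets an optional item (a nulled required item legitimately
yields two findings by design). The units-mismatch pair plants an NFC/NFD
variant so the normalization policy's purpose is demonstrable.

Determinism: one integer seed; per-file sub-seeds are the first four bytes
of SHA-256 over `"{seed}:{token}"`, so corpora are byte-identical across
runs and platforms, independent of Python's hash randomization.

## Numerical and degenerate-input choices

- Numeric grammar: `[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?`, full-match
  after stripping; `1,5`, `12 000` and `NaN` are non-numeric on purpose.
- Empty bodies are a distinct `empty_file` error, not a parse attempt.
- A measurement block whose two renditions differ in *presence* of rows is
  one `data_missing_in_json` finding, not hundreds of cell findings.
- Ties in heading rules are broken by table order after precedence rank.
- `equal_entries` is an equivalence relation for any fixed policy; the
  audit returning zero findings is equivalent to entry equality under the
  same policy (property-tested).

## Problem sizes

The shipped suites use 200 fixtures for round-trip identity, 25 fixtures
per defect class for the three detection suites (8 parse, 6 validation and
7 cross-format classes), 100 fixtures for order-preservation, and a
50-entry corpus for extraction recovery — sizes chosen so the whole suite
and the acceptance script each complete in seconds while still exercising
every generator branch (three analysis types, extended blocks,
results-file-only entries).

## Known limitations

- The lenient recovery path (keep-first on duplicate items) is not
  exposed; strict parsing is the only mode.
- The JSON dialect key spellings are config defaults, not a verified
  contract with the live service; `JSON_KEYS` exists to be overridden.
- No FTP retrieval of results files; `MS_RESULTS_FILE` is validated as a
  link convention only.
- Identifier *values* (HMDB/KEGG/PubChem accessions) are not checked
  against their registries; the standardizer maps headings, not values.
- The REST validity table is intentionally minimal and fails closed;
  mirroring the full live grammar is out of scope.
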