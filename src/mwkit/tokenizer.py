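"""Line-level scanner for the tab-delimited mwTab text format.

The scanner turns raw text into a typed stream of :class:`Line` tokens the
parser consumes.  It is lossless: every input line yields exactly one token
carrying the original text, so re-emitting ``raw`` reproduces the input
byte-for-byte.  Malformed lines are classified, never discarded — the parser
decides which structural defect class they belong to.

Dialect rules:

* the first line is the banner, ``#METABOLOMICS WORKBENCH`` followed by
  space-separated ``KEY:VALUE`` identifier tokens;
* ``#NAME`` lines open sections; ``#END`` terminates the file;
* item lines are ``KEY<tab...>VALUE`` — one or more tabs separate key and
  value; trailing spaces are stripped from the key, never from the value;
* ``NAME_START`` / ``NAME_END`` delimit tabular blocks, with an optional
  ``NAME:UNITS<tab>value`` line before the start;
* SUBJECT_SAMPLE_FACTORS records begin with that literal key and carry four
  further tab-separated fields.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import DATA_BLOCK_KINDS, SSF_SECTION_NAME

BANNER_PREFIX = "#METABOLOMICS WORKBENCH"
END_MARKER = "#END"

#: Line kinds emitted by :func:`tokenize`.
LINE_KINDS = (
    "header_banner",
    "section_header",
    "item",
    "ssf_record",
    "block_start",
    "block_end",
    "block_row",
    "units_line",
    "end_marker",
    "blank",
    "malformed",
)

_UNITS_RE = re.compile(r"^([A-Z0-9_]+):UNITS$")
_BANNER_TOKEN_RE = re.compile(r"(\S+?):(\S+)")


@dataclass
class Line:
    """One scanned input line: 1-based number, token kind, tab-split cells
    and the untouched original text."""

    number: int
    kind: str
    fields: list[str] = field(default_factory=list)
    raw: str = ""


@dataclass
class TokenizerDefect:
    """A line-level irregularity the scanner recovered from (e.g. tab runs
    inside the banner)."""

    code: str
    line_number: int
    detail: str = ""


def _block_name(cell: str, suffix: str) -> str | None:
    if cell.endswith(suffix):
        name = cell[: -len(suffix)]
        if name in DATA_BLOCK_KINDS:
            return name
    return None


def tokenize(text: str) -> list[Line]:
    """Scan ``text`` into one :class:`Line` per input line.

    No line is silently dropped; ``"\\n".join(line.raw for line in result)``
    reproduces the input exactly.
    """
    lines: list[Line] = []
    in_block: str | None = None
    for number, raw in enumerate(text.split("\n"), start=1):
        content = raw.rstrip("\r")
        cells = content.split("\t")
        first = cells[0]
        if content.strip() == "":
            kind = "blank"
        elif in_block is not None:
            if first == f"{in_block}_END" and len(cells) == 1:
                kind = "block_end"
                in_block = None
            else:
                kind = "block_row"
        elif content.startswith(BANNER_PREFIX):
            kind = "header_banner"
        elif content == END_MARKER:
            kind = "end_marker"
        elif content.startswith("#"):
            kind = "section_header"
            cells = [content[1:].split("\t")[0].strip()]
        elif first == SSF_SECTION_NAME:
            kind = "ssf_record"
        elif len(cells) == 1:
            started = _block_name(first, "_START")
            if started is not None:
                kind = "block_start"
                in_block = started
                cells = [started]
            else:
                kind = "malformed"
        elif _UNITS_RE.match(first):
            kind = "units_line"
        else:
            kind = "item"
        lines.append(Line(number=number, kind=kind, fields=cells, raw=raw))
    return lines


def item_key_value(line: Line) -> tuple[str, str]:
    """Split an item line into (key, value).

    The key is everything before the first tab run, with trailing spaces
    stripped (padded layouts); the value is everything after it, verbatim.
    """
    content = line.raw.rstrip("\r")
    key, _, rest = content.partition("\t")
    return key.rstrip(), rest.lstrip("\t")


def classify_header_banner(line: Line) -> tuple[dict[str, str], list[TokenizerDefect]]:
    """Extract the ``KEY:VALUE`` identifier tokens from the banner line.

    Repeated tabs inside the banner are collapsed to single spaces before
    tokenizing, and recorded as an ``excessive_tabs`` defect so strict
    callers can reject the file while lenient ones recover the identifiers.
    """
    if line.kind != "header_banner":
        raise ValueError("not a banner line")
    defects: list[TokenizerDefect] = []
    content = line.raw.rstrip("\r")
    if "\t" in content:
        defects.append(TokenizerDefect(
            code="excessive_tabs",
            line_number=line.number,
            detail=f"{content.count(chr(9))} tab characters in banner",
        ))
        content = re.sub(r"\t+", " ", content)
    remainder = content[len(BANNER_PREFIX):]
    ids = {match.group(1): match.group(2)
           for match in _BANNER_TOKEN_RE.finditer(remainder)}
    return ids, defects
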