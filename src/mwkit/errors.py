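"""Exception hierarchy shared across the package.

Parse failures carry a machine-readable ``code`` (one per defect class) and a
1-based ``line_number`` locating the offending line, so that callers can tally
failure classes across a corpus without string-matching messages.
"""

from __future__ import annotations


class MWKitError(Exception):
    """Base class for all package errors."""


class ParseError(MWKitError):
    """A structural defect that prevents a file from being parsed.

    Parameters
    ----------
    code:
        Machine-readable defect class, e.g. ``"ssf_malformed"`` or
        ``"missing_banner"``.
    line_number:
        1-based line index of the defect (0 when no single line applies,
        e.g. an empty file).
    message:
        Human-readable description.
    """

    def __init__(self, code: str, line_number: int = 0, message: str = ""):
        self.code = code
        self.line_number = line_number
        super().__init__(message or f"parse error [{code}] at line {line_number}")


class SerializationError(MWKitError):
    """An entry violating model invariants cannot be written out."""


class RetrievalError(MWKitError):
    """A transport-level failure (non-200 status, unreachable host)."""

    def __init__(self, url: str, status: int | None = None, message: str = ""):
        self.url = url
        self.status = status
        super().__init__(message or f"retrieval failed for {url} (status={status})")


class ParameterError(MWKitError):
    """Invalid REST parameters: unknown context or an invalid triple."""

    def __init__(self, key: str, message: str = ""):
        self.key = key
        super().__init__(message or f"invalid REST parameter: {key}")


class InjectionError(MWKitError):
    """A defect class cannot be injected into the given artifact."""
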