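"""Metabolomics Workbench REST URL construction and bulk retrieval.

A REST request URL is three parts joined as path segments under the
documented root: a context (study, compound, ...), an input specification
(input item + input value) and an output specification (output item +
output format), e.g.::

    https://www.metabolomicsworkbench.org/rest/study/analysis_id/AN000002/mwtab/txt

The (context, input_item, output_item) triple is checked against a shipped
validity table seeded from the demonstrated combinations; unknown
combinations fail closed unless ``strict=False``.

All network access goes through an injectable transport — an object with
``fetch(url) -> (status, body)`` — so retrieval logic is testable offline
with :class:`MockTransport`.
"""

from __future__ import annotations

import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Protocol

from . import config
from .errors import ParameterError, RetrievalError

_ANALYSIS_ID_RE = re.compile(r"AN\d+")
_ID_RE = re.compile(r"(AN|ST)\d+")


class Transport(Protocol):
    """Minimal retrieval contract: ``fetch(url) -> (status, body text)``."""

    def fetch(self, url: str) -> tuple[int, str]:  # pragma: no cover - protocol
        ...


class HttpTransport:
    """urllib-based transport with a courteous inter-request delay and
    bounded exponential-backoff retry."""

    def __init__(self, delay: float = 0.5, retries: int = 3, timeout: float = 30.0):
        self.delay = delay
        self.retries = retries
        self.timeout = timeout
        self._last_request = 0.0

    def fetch(self, url: str) -> tuple[int, str]:
        import urllib.error
        import urllib.request

        wait = self.delay - (time.monotonic() - self._last_request)
        if wait > 0:
            time.sleep(wait)
        backoff = 1.0
        for attempt in range(self.retries):
            self._last_request = time.monotonic()
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as response:
                    return response.status, response.read().decode("utf-8")
            except urllib.error.HTTPError as exc:
                return exc.code, ""
            except urllib.error.URLError:
                if attempt == self.retries - 1:
                    raise RetrievalError(url, None, f"unreachable: {url}")
                time.sleep(backoff)
                backoff *= 2
        raise RetrievalError(url, None)  # pragma: no cover - unreachable


class MockTransport:
    """Offline transport serving canned bodies from a url -> body mapping.

    Unknown URLs return 404.  ``calls`` records every fetched URL in order.
    """

    def __init__(self, responses: dict[str, str] | None = None,
                 default_status: int = 404):
        self.responses = dict(responses or {})
        self.default_status = default_status
        self.calls: list[str] = []

    def fetch(self, url: str) -> tuple[int, str]:
        self.calls.append(url)
        if url in self.responses:
            return 200, self.responses[url]
        return self.default_status, ""


@dataclass
class RestUrl:
    """A validated REST request: context, input and output specifications."""

    context: str
    input_item: str
    input_value: str
    output_item: str
    output_format: str = "txt"
    base: str = config.REST_BASE_URL

    @property
    def url(self) -> str:
        base = self.base if self.base.endswith("/") else self.base + "/"
        segments = [self.context, self.input_item, self.input_value,
                    self.output_item]
        if self.output_format:
            segments.append(self.output_format)
        return base + "/".join(segments)

    def __str__(self) -> str:
        return self.url


def _validate_params(context: str, input_item: str, output_item: str,
                     output_format: str,
                     table: dict | None = None) -> None:
    table = table if table is not None else config.REST_VALIDITY_TABLE
    if context not in table:
        raise ParameterError("context", f"unknown REST context: {context!r}")
    spec = table[context]
    if input_item not in spec["input_items"]:
        raise ParameterError(
            "input_item",
            f"input item {input_item!r} is not valid for context {context!r}")
    if output_item not in spec["output_items"]:
        raise ParameterError(
            "output_item",
            f"output item {output_item!r} is not valid for context {context!r}")
    if output_format and output_format not in spec["output_formats"]:
        raise ParameterError(
            "output_format", f"unknown output format: {output_format!r}")


def build_url(params: dict[str, str], base: str = config.REST_BASE_URL,
              strict: bool = True,
              table: dict | None = None) -> RestUrl:
    """Build a validated :class:`RestUrl` from a REST parameter mapping.

    ``params`` must provide ``context``, ``input_item``, ``input_value`` and
    ``output_item`` (plus optional ``output_format``).  With ``strict`` the
    triple must appear in the validity table; ``strict=False`` overrides the
    fail-closed default for combinations the table does not yet know.
    """
    missing = [k for k in ("context", "input_item", "input_value", "output_item")
               if not params.get(k)]
    if missing:
        raise ParameterError(missing[0], f"missing REST parameter: {missing[0]}")
    output_format = params.get("output_format", "txt")
    if strict:
        _validate_params(params["context"], params["input_item"],
                         params["output_item"], output_format, table)
    return RestUrl(
        context=params["context"],
        input_item=params["input_item"],
        input_value=params["input_value"],
        output_item=params["output_item"],
        output_format=output_format,
        base=base,
    )


def parse_url(url: str, base: str = config.REST_BASE_URL) -> dict[str, str]:
    """Invert :attr:`RestUrl.url`: recover the parameter mapping from a
    rendered URL string (bijective on valid inputs)."""
    base = base if base.endswith("/") else base + "/"
    if not url.startswith(base):
        raise ParameterError("base", f"URL does not start with {base!r}")
    segments = url[len(base):].split("/")
    if len(segments) not in (4, 5):
        raise ParameterError("url", f"expected 4 or 5 path segments, got {len(segments)}")
    params = {
        "context": segments[0],
        "input_item": segments[1],
        "input_value": segments[2],
        "output_item": segments[3],
    }
    if len(segments) == 5:
        params["output_format"] = segments[4]
    return params


def generate_entry_urls(ids: Iterable[str], output_format: str = "txt",
                        base: str = config.REST_BASE_URL) -> Iterator[RestUrl]:
    """One mwtab-output URL per analysis (ANnnnnnn) or study (STnnnnnn) ID."""
    for identifier in ids:
        if not _ID_RE.fullmatch(identifier):
            raise ParameterError("id", f"malformed analysis/study ID: {identifier!r}")
        input_item = "analysis_id" if identifier.startswith("AN") else "study_id"
        yield build_url({
            "context": "study",
            "input_item": input_item,
            "input_value": identifier,
            "output_item": "mwtab",
            "output_format": output_format,
        }, base=base)


def analysis_listing_url(base: str = config.REST_BASE_URL) -> str:
    base = base if base.endswith("/") else base + "/"
    return base + config.REST_ANALYSIS_LISTING_PATH


def enumerate_analysis_ids(transport: Transport,
                           base: str = config.REST_BASE_URL) -> list[str]:
    """Retrieve the available analysis IDs: parsed, deduplicated, ascending.

    The listing endpoint may answer with plain text or JSON; both shapes are
    accepted (IDs are recognized anywhere in the body).
    """
    url = analysis_listing_url(base)
    status, body = transport.fetch(url)
    if status != 200:
        raise RetrievalError(url, status)
    try:
        body = json.dumps(json.loads(body))
    except (json.JSONDecodeError, TypeError):
        pass
    return sorted(set(_ANALYSIS_ID_RE.findall(body)))


@dataclass
class DownloadManifest:
    """Per-ID outcome of a bulk download: ok | blank_body | retrieval_error."""

    statuses: dict[str, str] = field(default_factory=dict)

    def count(self, status: str) -> int:
        return sum(1 for s in self.statuses.values() if s == status)

    def to_json(self) -> str:
        return json.dumps(self.statuses, indent=1, sort_keys=True)


def download_all(transport: Transport, destination: str | Path,
                 output_format: str = "txt", resume: bool = False,
                 base: str = config.REST_BASE_URL) -> DownloadManifest:
    """Download every available analysis entry into ``destination``.

    Blank bodies are recorded as ``blank_body`` and not saved as entries;
    per-ID retrieval failures are recorded, never fatal.  With ``resume``,
    IDs whose files already exist non-empty are skipped (idempotent).
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    manifest = DownloadManifest()
    for identifier in enumerate_analysis_ids(transport, base):
        target = destination / f"{identifier}.{output_format}"
        if resume and target.exists() and target.stat().st_size > 0:
            manifest.statuses[identifier] = "ok"
            continue
        rest_url = next(generate_entry_urls([identifier], output_format, base))
        status, body = transport.fetch(rest_url.url)
        if status != 200:
            manifest.statuses[identifier] = "retrieval_error"
        elif body.strip() == "":
            manifest.statuses[identifier] = "blank_body"
        else:
            target.write_text(body, encoding="utf-8")
            manifest.statuses[identifier] = "ok"
    (destination / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest
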