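"""Minimal response-id path dialect: dot-separated keys, ``[]`` maps arrays.

An annotated operation declares where output identifiers live in an API
response with an expression such as ``"hits[].id"`` or
``"data.associations[].object.id"``. The dialect is intentionally small —
object keys separated by dots, where a ``[]`` suffix maps the rest of the
path over every element of an array — so that the whole language is
specifiable and testable. Missing keys, non-dict lookups and non-list ``[]``
targets yield no results rather than errors; extraction preserves document
order and duplicates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import IdPathError

__all__ = ["PathSegment", "IdPath", "parse_id_path", "extract_ids"]

_SEGMENT_RE = re.compile(r"^([^.\[\]]+)(\[\])?$")


@dataclass(frozen=True)
class PathSegment:
    key: str
    is_array: bool


@dataclass(frozen=True)
class IdPath:
    """A parsed path expression."""

    segments: tuple[PathSegment, ...]
    source: str

    def __str__(self) -> str:
        return self.source


def parse_id_path(expr: str) -> IdPath:
    """Parse ``expr``; raises :class:`IdPathError` on any syntax problem.

    Path syntax errors are a registry-load-time concern: operations are
    validated when their spec is parsed, never during query execution.
    """
    if not isinstance(expr, str) or not expr.strip():
        raise IdPathError(f"empty response_id_path {expr!r}")
    segments = []
    for part in expr.split("."):
        match = _SEGMENT_RE.match(part)
        if not match:
            raise IdPathError(f"bad path segment {part!r} in {expr!r}")
        segments.append(PathSegment(key=match.group(1), is_array=match.group(2) == "[]"))
    return IdPath(segments=tuple(segments), source=expr)


def _walk(node: object, segments: tuple[PathSegment, ...], out: list[str]) -> None:
    if not segments:
        if isinstance(node, (str, int, float)) and not isinstance(node, bool):
            out.append(str(node))
        return
    head, rest = segments[0], segments[1:]
    if not isinstance(node, dict) or head.key not in node:
        return
    value = node[head.key]
    if head.is_array:
        if isinstance(value, list):
            for item in value:
                _walk(item, rest, out)
    else:
        _walk(value, rest, out)


def extract_ids(document: object, path: IdPath | str) -> list[str]:
    """Extract output identifier strings from a parsed response document."""
    if isinstance(path, str):
        path = parse_id_path(path)
    out: list[str] = []
    _walk(document, path.segments, out)
    return out
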