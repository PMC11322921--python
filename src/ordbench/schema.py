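"""Data model for the modeled ORD schema subset.

A reaction record is a nested "message" tree in the style of the Open
Reaction Database (ORD): dictionaries of typed fields, repeated messages
(lists), and one map-valued field (``inputs``).  The model here is
data-driven: a :class:`SchemaSpec` vocabulary file declares every admitted
field path, its kind, and — for enum fields — the exact strings the field
accepts.  Records live as plain JSON; this module parses them into
path-addressable :class:`MessageNode` trees, validates them against the
vocabulary, and flattens them to leaf fields, the unit of field-level
scoring.

Path convention: dotted field names, zero-based bracketed list indices,
and double-quoted map keys, e.g.::

    inputs["m1"].components[0].identifiers[0].value
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterator

__all__ = [
    "JSONParseError",
    "SchemaError",
    "SchemaField",
    "SchemaSpec",
    "MessageNode",
    "Violation",
    "ValidationReport",
    "parse_record",
    "validate_record",
    "leaf_fields",
    "count_leaves",
    "iter_leaves",
    "render_path",
    "path_pattern",
]

KINDS = {
    "scalar-string",
    "scalar-number",
    "enum",
    "message",
    "repeated-message",
    "map-of-message",
}


class JSONParseError(ValueError):
    """Raised when record text is not syntactically valid JSON.

    Distinct from schema validation failure, which is reported, never raised.
    """


class SchemaError(ValueError):
    """Raised for an ill-formed SchemaSpec (duplicate paths, empty enums)."""


@dataclass(frozen=True)
class SchemaField:
    path: str  # pattern form: '*' for map keys, '[]' for list indices
    kind: str
    enum_vocab: tuple[str, ...] = ()


class SchemaSpec:
    """Declarative description of the modeled schema subset."""

    def __init__(self, fields: list[SchemaField], version: str = "unversioned"):
        self.version = version
        self.fields: dict[str, SchemaField] = {}
        for f in fields:
            if f.kind not in KINDS:
                raise SchemaError(f"unknown field kind {f.kind!r} at {f.path!r}")
            if f.path in self.fields:
                raise SchemaError(f"duplicate schema path {f.path!r}")
            if f.kind == "enum" and not f.enum_vocab:
                raise SchemaError(f"enum field {f.path!r} has an empty vocabulary")
            self.fields[f.path] = f

    @classmethod
    def from_dict(cls, d: dict) -> "SchemaSpec":
        fields = [
            SchemaField(e["path"], e["kind"], tuple(e.get("enum", ())))
            for e in d["fields"]
        ]
        return cls(fields, version=str(d.get("version", "unversioned")))

    @classmethod
    def from_file(cls, path: str) -> "SchemaSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "SchemaSpec":
        """The vocabulary shipped with the package."""
        text = (
            resources.files("ordbench")
            .joinpath("data/schema_vocab.json")
            .read_text(encoding="utf-8")
        )
        return cls.from_dict(json.loads(text))

    def lookup(self, pattern: str) -> SchemaField | None:
        return self.fields.get(pattern)

    def is_map(self, pattern: str) -> bool:
        f = self.fields.get(pattern)
        return f is not None and f.kind == "map-of-message"


# ---------------------------------------------------------------------------
# Paths.  Internally a path is a tuple of segments:
#   ("f", name) field, ("i", idx) list index, ("k", key) map key.
# ---------------------------------------------------------------------------

Segment = tuple[str, Any]
Path = tuple[Segment, ...]


def render_path(path: Path) -> str:
    parts: list[str] = []
    for tag, val in path:
        if tag == "f":
            parts.append(("." if parts else "") + val)
        elif tag == "i":
            parts.append(f"[{val}]")
        else:  # map key
            parts.append(f'["{val}"]')
    return "".join(parts)


def path_pattern(path: Path) -> str:
    """Collapse a concrete path to its schema pattern form."""
    parts: list[str] = []
    for tag, val in path:
        if tag == "f":
            parts.append(("." if parts else "") + val)
        elif tag == "i":
            parts.append("[]")
        else:
            parts.append(("." if parts else "") + "*")
    return "".join(parts)


def _strip_nulls(value: Any) -> Any:
    """Drop explicit nulls and empty containers so 'populated' is well defined."""
    if isinstance(value, dict):
        out = {}
        for k, v in value.items():
            sv = _strip_nulls(v)
            if sv is not None:
                out[k] = sv
        return out if out else None
    if isinstance(value, list):
        out_l = [sv for sv in (_strip_nulls(v) for v in value) if sv is not None]
        return out_l if out_l else None
    return value


@dataclass
class MessageNode:
    """A path-addressable tree holding one message; the unit of diffing."""

    data: Any
    message_type: str = "Reaction"
    spec: SchemaSpec | None = field(default=None, repr=False, compare=False)

    def is_empty(self) -> bool:
        return self.data is None

    def leaves(self) -> list[tuple[str, Any]]:
        return leaf_fields(self)

    def to_json(self, *, indent: int | None = None) -> str:
        """Canonical serialization: sorted keys, no trailing whitespace."""
        return json.dumps(
            self.data if self.data is not None else {},
            sort_keys=True,
            indent=indent,
            ensure_ascii=False,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MessageNode):
            return NotImplemented
        return self.data == other.data and self.message_type == other.message_type


def parse_record(
    json_text: str,
    spec: SchemaSpec | None = None,
    message_type: str = "Reaction",
) -> MessageNode:
    """Parse record JSON into a MessageNode.

    Explicit nulls and empty containers are stripped so that every retained
    leaf is a populated field.  Unknown fields are retained in the tree and
    flagged later by :func:`validate_record`.  Malformed JSON raises
    :class:`JSONParseError` — a parse failure, distinct from a validation
    failure.
    """
    try:
        raw = json.loads(json_text)
    except json.JSONDecodeError as e:
        raise JSONParseError(str(e)) from e
    if not isinstance(raw, dict):
        raise JSONParseError(f"record root must be an object, got {type(raw).__name__}")
    data = _strip_nulls(raw)
    return MessageNode(data=data, message_type=message_type, spec=spec)


def iter_leaves(data: Any, prefix: Path = (), spec: SchemaSpec | None = None) -> Iterator[tuple[Path, Any]]:
    """Depth-first, index-ordered enumeration of populated leaves."""
    if data is None:
        return
    if isinstance(data, dict):
        pattern = path_pattern(prefix)
        as_map = spec is not None and spec.is_map(pattern)
        tag = "k" if as_map else "f"
        for key, val in data.items():
            yield from iter_leaves(val, prefix + ((tag, key),), spec)
    elif isinstance(data, list):
        for i, val in enumerate(data):
            yield from iter_leaves(val, prefix + (("i", i),), spec)
    else:
        yield prefix, data


def leaf_fields(node: MessageNode) -> list[tuple[str, Any]]:
    """Flatten a node to ``(path, value)`` pairs over populated leaves only."""
    return [
        (render_path(p), v) for p, v in iter_leaves(node.data, spec=node.spec)
    ]


def count_leaves(data: Any) -> int:
    if data is None:
        return 0
    if isinstance(data, dict):
        return sum(count_leaves(v) for v in data.values())
    if isinstance(data, list):
        return sum(count_leaves(v) for v in data)
    return 1


@dataclass(frozen=True)
class Violation:
    path: str
    kind: str  # out-of-vocabulary enum | wrong scalar type | unknown field
    value: Any


@dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def is_valid(self) -> bool:
        return not self.violations


def _check(data: Any, prefix: Path, spec: SchemaSpec, out: list[Violation]) -> None:
    pattern = path_pattern(prefix)
    f = spec.lookup(pattern) if prefix else None

    named = bool(prefix) and prefix[-1][0] == "f"  # list items / map values have no own entry

    if isinstance(data, dict):
        if named and f is None:
            # unknown branch: flag every leaf under it
            for p, v in iter_leaves(data, prefix, spec):
                out.append(Violation(render_path(p), "unknown field", v))
            return
        if named and f.kind not in ("message", "map-of-message"):
            out.append(Violation(render_path(prefix), "wrong scalar type", data))
            return
        tag = "k" if spec.is_map(pattern) else "f"
        for key, val in data.items():
            _check(val, prefix + ((tag, key),), spec, out)
        return

    if isinstance(data, list):
        if named and f is None:
            for p, v in iter_leaves(data, prefix, spec):
                out.append(Violation(render_path(p), "unknown field", v))
            return
        if named and f.kind != "repeated-message":
            out.append(Violation(render_path(prefix), "wrong scalar type", data))
            return
        for i, val in enumerate(data):
            _check(val, prefix + (("i", i),), spec, out)
        return

    # scalar leaf
    if f is None:
        out.append(Violation(render_path(prefix), "unknown field", data))
    elif f.kind == "enum":
        # case-sensitive exact membership, mirroring protobuf enum strictness
        if not isinstance(data, str) or data not in f.enum_vocab:
            out.append(Violation(render_path(prefix), "out-of-vocabulary enum", data))
    elif f.kind == "scalar-number":
        if isinstance(data, bool) or not isinstance(data, (int, float)):
            out.append(Violation(render_path(prefix), "wrong scalar type", data))
    elif f.kind == "scalar-string":
        if not isinstance(data, str):
            out.append(Violation(render_path(prefix), "wrong scalar type", data))
    else:
        # a message-kind field holding a scalar
        out.append(Violation(render_path(prefix), "wrong scalar type", data))


def validate_record(node: MessageNode, spec: SchemaSpec) -> ValidationReport:
    """Syntactic validation: one violation per offending leaf; never raises."""
    out: list[Violation] = []
    if node.data is not None:
        _check(node.data, (), spec, out)
    return ValidationReport(violations=out)
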