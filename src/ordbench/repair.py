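"""Heuristic repair of malformed JSON completions.

Language models occasionally emit near-JSON: a missing quote or comma, an
unclosed bracket, a bare enum string.  Valid input is a byte-identical
fixed point; anything else is re-parsed by a single left-to-right lenient
pass that tolerates unterminated strings, unquoted keys and values,
missing commas and colons, trailing commas, mismatched or missing closing
brackets, and trailing garbage, then re-serialized as valid JSON.  Content
is never reordered; repairs are local insertions/deletions recorded as an
action log.  Semantic repair (wrong field names, hallucinated fields) is
out of scope — counting those is the evaluator's job.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

__all__ = ["RepairResult", "repair_json"]

_MISSING = object()

_NUMBER_RE = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?")
_ESCAPES = {'"': '"', "\\": "\\", "/": "/", "b": "\b", "f": "\f",
            "n": "\n", "r": "\r", "t": "\t"}


@dataclass
class RepairResult:
    repaired_text: str
    actions: list[tuple[int, str]] = field(default_factory=list)
    success: bool = False


class _Lenient:
    """Single-pass tolerant JSON reader with an action log."""

    def __init__(self, text: str):
        self.s = text
        self.n = len(text)
        self.i = 0
        self.actions: list[tuple[int, str]] = []

    def note(self, action: str, pos: int | None = None) -> None:
        self.actions.append((self.i if pos is None else pos, action))

    def ws(self) -> None:
        while self.i < self.n and self.s[self.i] in " \t\r\n":
            self.i += 1

    def peek(self) -> str:
        return self.s[self.i] if self.i < self.n else ""

    # -- values ------------------------------------------------------------

    def value(self):
        self.ws()
        c = self.peek()
        if c == "":
            return _MISSING
        if c == "{":
            return self.obj()
        if c == "[":
            return self.arr()
        if c in "\"'":
            return self.string(c)
        if c.isdigit() or c in "-+.":
            return self.number()
        if c.isalpha() or c == "_":
            return self.bareword()
        return _MISSING  # caller decides how to handle stray structure

    def string(self, quote: str) -> str:
        self.i += 1
        buf: list[str] = []
        while self.i < self.n:
            c = self.s[self.i]
            if c == quote:
                self.i += 1
                return "".join(buf)
            if c == "\\" and self.i + 1 < self.n:
                nxt = self.s[self.i + 1]
                if nxt in _ESCAPES:
                    buf.append(_ESCAPES[nxt])
                    self.i += 2
                    continue
                if nxt == "u" and self.i + 5 < self.n:
                    hexpart = self.s[self.i + 2 : self.i + 6]
                    try:
                        buf.append(chr(int(hexpart, 16)))
                        self.i += 6
                        continue
                    except ValueError:
                        pass
                buf.append(nxt)
                self.i += 2
                continue
            if c == "\n":
                # unterminated string: close at end of line
                self.note("insert-quote")
                return "".join(buf)
            buf.append(c)
            self.i += 1
        self.note("insert-quote")  # ran to end of text
        return "".join(buf)

    def number(self):
        m = _NUMBER_RE.match(self.s, self.i)
        if m:
            self.i = m.end()
            text = m.group(0)
            try:
                return int(text)
            except ValueError:
                return float(text)
        return self.bareword()

    def bareword(self):
        start = self.i
        while self.i < self.n and self.s[self.i] not in ",:]}\n":
            self.i += 1
        word = self.s[start : self.i].strip()
        if word == "true":
            return True
        if word == "false":
            return False
        if word in ("null", ""):
            return None
        try:
            return int(word)
        except ValueError:
            pass
        try:
            return float(word)
        except ValueError:
            pass
        self.note("insert-quote", start)
        return word

    # -- containers --------------------------------------------------------

    def obj(self) -> dict:
        self.i += 1  # consume '{'
        out: dict = {}
        while True:
            self.ws()
            c = self.peek()
            if c == "":
                self.note("insert-bracket")
                return out
            if c == "}":
                self.i += 1
                return out
            if c == ",":
                self.i += 1
                continue
            if c == "]":
                self.i += 1  # stray closer inside an object
                self.note("truncate-garbage")
                continue
            key = self.key()
            self.ws()
            if self.peek() == ":":
                self.i += 1
            else:
                self.note("insert-comma")  # missing colon; treat next as value
            self.ws()
            if self.peek() in ",}":
                out[key] = None
                continue
            val = self.value()
            out[key] = None if val is _MISSING else val
            if val is _MISSING and self.peek() not in ",}]" and self.peek() != "":
                self.i += 1  # skip an unusable character to guarantee progress
                self.note("truncate-garbage")

    def key(self) -> str:
        c = self.peek()
        if c in "\"'":
            return self.string(c)
        start = self.i
        while self.i < self.n and self.s[self.i] not in ":,]}{[\n\"":
            self.i += 1
        if self.i == start:
            self.i += 1  # stray structural char where a key should be
            self.note("truncate-garbage")
            return self.key() if self.i < self.n else ""
        self.note("insert-quote", start)
        return self.s[start : self.i].strip()

    def arr(self) -> list:
        self.i += 1  # consume '['
        out: list = []
        while True:
            self.ws()
            c = self.peek()
            if c == "":
                self.note("insert-bracket")
                return out
            if c == "]":
                self.i += 1
                return out
            if c == "}":
                # mismatched closer: close the array, let the outer object
                # consume the brace
                self.note("insert-bracket")
                return out
            if c == ",":
                self.i += 1
                continue
            if c == ":":
                self.i += 1
                self.note("truncate-garbage")
                continue
            val = self.value()
            if val is _MISSING:
                if self.peek() not in ",]}" and self.peek() != "":
                    self.i += 1
                    self.note("truncate-garbage")
                continue
            out.append(val)


def _trailing_comma_cleanup(text: str) -> str:
    return re.sub(r",(\s*[}\]])", r"\1", text)


def repair_json(text: str) -> RepairResult:
    """Repair near-JSON into valid JSON.

    Valid input is returned unchanged with an empty action log, making the
    function idempotent on its own successful output.  Failure (no value
    recoverable at all) is a result state, never an exception.
    """
    try:
        json.loads(text)
        return RepairResult(repaired_text=text, actions=[], success=True)
    except (json.JSONDecodeError, ValueError):
        pass

    # cheap fix first: a trailing comma is the only defect in many outputs
    cleaned = _trailing_comma_cleanup(text)
    if cleaned != text:
        try:
            json.loads(cleaned)
            return RepairResult(
                repaired_text=cleaned,
                actions=[(0, "delete-trailing-comma")],
                success=True,
            )
        except (json.JSONDecodeError, ValueError):
            pass

    p = _Lenient(text)
    val = p.value()
    p.ws()
    if val is not _MISSING and p.i < p.n and p.peek() == ":":
        # a deleted root '{': re-read with the brace restored
        p = _Lenient("{" + text)
        p.note("insert-bracket", 0)
        val = p.value()
        p.ws()
    if p.i < p.n:
        p.note("truncate-garbage")
    if val is _MISSING:
        return RepairResult(repaired_text=text, actions=p.actions, success=False)
    repaired = json.dumps(val, ensure_ascii=False)
    return RepairResult(repaired_text=repaired, actions=p.actions, success=True)
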