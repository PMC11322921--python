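"""JSON-lines readers/writers for corpora, examples, and predictions."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Iterator

from .prep import CorpusRecord, PromptExample
from .schema import MessageNode, SchemaSpec

__all__ = [
    "write_corpus",
    "read_corpus",
    "write_examples",
    "read_examples",
    "read_predictions",
]


def write_corpus(records: Iterable[CorpusRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "source_id": rec.source_id,
                        "procedure_text": rec.procedure_text,
                        "record": rec.record.data or {},
                    },
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )


def read_corpus(path: str | Path, spec: SchemaSpec | None = None) -> list[CorpusRecord]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            node = MessageNode(
                data=obj.get("record") or None, message_type="Reaction", spec=spec
            )
            out.append(
                CorpusRecord(
                    record=node,
                    procedure_text=obj.get("procedure_text", ""),
                    source_id=obj.get("source_id", ""),
                )
            )
    return out


def write_examples(examples: Iterable[PromptExample], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ex in examples:
            fh.write(json.dumps(asdict(ex), ensure_ascii=False) + "\n")


def read_examples(path: str | Path) -> list[PromptExample]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(PromptExample(**json.loads(line)))
    return out


def read_predictions(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (source_id, completion text) pairs.

    Each line is either ``{"source_id": ..., "completion": "<json text>"}``
    or ``{"source_id": ..., "record": {...}}``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            sid = obj.get("source_id", "")
            if "completion" in obj:
                yield sid, obj["completion"]
            else:
                yield sid, json.dumps(obj.get("record") or {}, ensure_ascii=False)
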