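"""Corpus preparation: admission, implicit-information scrubbing, prompt
rendering, deduplication, token-length filtering, and train/val/test split.

A corpus record pairs a structured reaction record with the free-text
procedure paragraph it was derived from.  Records are admitted only when
every reaction input actually lists its components and a procedure
paragraph is present.  Structured content that a text-to-record extractor
could never learn — a product name that the paragraph never states, a
calculated yield that differs from the reported one — is scrubbed before
the pair is rendered into an instruction-style prompt/completion example.
"""

from __future__ import annotations

import copy
import logging
import random
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

from .reports import pct
from .schema import MessageNode, _strip_nulls

__all__ = [
    "CorpusRecord",
    "PromptExample",
    "PrepReport",
    "ConfigError",
    "DEFAULT_INSTRUCTION",
    "default_template",
    "default_tokenizer",
    "admit_record",
    "scrub_implicit",
    "render_prompt",
    "dedupe",
    "token_filter",
    "split",
    "prep_report",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class CorpusRecord:
    record: MessageNode
    procedure_text: str
    source_id: str = ""


@dataclass
class PromptExample:
    prompt: str
    completion: str
    token_count: int = 0
    split: str = "none"  # train | validation | test | none
    source_id: str = ""


@dataclass
class PrepReport:
    n_in: int
    n_admitted: int
    n_unique: int
    n_within_limit: int
    retention_pct: float | None = None
    seed: int | None = None
    metadata: dict = field(default_factory=dict)


DEFAULT_INSTRUCTION = (
    "Extract the structured reaction record, as JSON following the Open "
    "Reaction Database schema, from the following procedure text."
)

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def default_tokenizer(text: str) -> int:
    """Deterministic whitespace-plus-punctuation token count.

    A stand-in contract for a subword tokenizer; counts are documented as
    tokenizer-dependent and any ``str -> int`` callable may be plugged in.
    """
    return len(_TOKEN_RE.findall(text))


def default_template() -> str:
    return (
        resources.files("ordbench")
        .joinpath("data/prompt_template.txt")
        .read_text(encoding="utf-8")
    )


# ---------------------------------------------------------------------------
# Admission and scrubbing
# ---------------------------------------------------------------------------


def admit_record(rec: CorpusRecord) -> bool:
    """True iff every reaction input lists at least one component and the
    procedure text is a non-empty paragraph."""
    if not rec.procedure_text or not rec.procedure_text.strip():
        return False
    data = rec.record.data or {}
    for inp in (data.get("inputs") or {}).values():
        if not (isinstance(inp, dict) and inp.get("components")):
            return False
    return True


def _normalize_ws(s: str) -> str:
    return re.sub(r"\s+", " ", s).strip()


def _name_in_text(name: str, text_norm_lower: str) -> bool:
    # case-insensitive substring search after whitespace normalization
    return _normalize_ws(name).lower() in text_norm_lower


def _yield_in_text(value: float, text: str) -> bool:
    # the integer part as a decimal string, under word-boundary search
    needle = str(int(value))
    return re.search(rf"(?<!\d){re.escape(needle)}(?!\d)", text) is not None


def _scrub_compound_names(
    compound: dict, text_norm_lower: str, base_path: str, removed: list[str]
) -> None:
    ids = compound.get("identifiers")
    if not ids:
        return
    kept = []
    for i, ident in enumerate(ids):
        if (
            isinstance(ident, dict)
            and ident.get("type") == "NAME"
            and isinstance(ident.get("value"), str)
            and not _name_in_text(ident["value"], text_norm_lower)
        ):
            removed.append(f"{base_path}.identifiers[{i}]")
        else:
            kept.append(ident)
    if kept:
        compound["identifiers"] = kept
    else:
        compound.pop("identifiers", None)


def scrub_implicit(rec: CorpusRecord) -> tuple[CorpusRecord, list[str]]:
    """Remove unlearnable implicit information, logging removals by path.

    Two rules: a NAME identifier (of an input compound or a product) whose
    value never occurs in the procedure paragraph is dropped; a YIELD
    measurement whose integer value is not stated in the paragraph is
    dropped.  Idempotent: a second pass removes nothing.
    """
    data = copy.deepcopy(rec.record.data) or {}
    text = rec.procedure_text
    text_norm_lower = _normalize_ws(text).lower()
    removed: list[str] = []

    for key, inp in (data.get("inputs") or {}).items():
        for ci, comp in enumerate(inp.get("components") or []):
            if isinstance(comp, dict):
                _scrub_compound_names(
                    comp, text_norm_lower, f'inputs["{key}"].components[{ci}]', removed
                )

    for oi, outcome in enumerate(data.get("outcomes") or []):
        for pi, prod in enumerate(outcome.get("products") or []):
            if not isinstance(prod, dict):
                continue
            base = f"outcomes[{oi}].products[{pi}]"
            _scrub_compound_names(prod, text_norm_lower, base, removed)
            meas = prod.get("measurements")
            if not meas:
                continue
            kept = []
            for mi, m in enumerate(meas):
                val = (
                    m.get("percentage", {}).get("value")
                    if isinstance(m, dict) and m.get("type") == "YIELD"
                    else None
                )
                if val is not None and not _yield_in_text(val, text):
                    removed.append(f"{base}.measurements[{mi}]")
                else:
                    kept.append(m)
            if kept:
                prod["measurements"] = kept
            else:
                prod.pop("measurements", None)

    node = MessageNode(
        data=_strip_nulls(data),  # containers emptied by scrubbing become absent
        message_type=rec.record.message_type,
        spec=rec.record.spec,
    )
    return CorpusRecord(node, rec.procedure_text, rec.source_id), removed


# ---------------------------------------------------------------------------
# Prompt rendering, dedup, token filter, split
# ---------------------------------------------------------------------------


def render_prompt(
    rec: CorpusRecord,
    template: str | None = None,
    instruction: str = DEFAULT_INSTRUCTION,
    tokenizer: Callable[[str], int] = default_tokenizer,
) -> PromptExample:
    """Deterministically render a record into a prompt/completion pair.

    The completion is the record's canonical JSON serialization; the prompt
    is everything the template places before the completion slot.
    """
    template = template if template is not None else default_template()
    for ph in ("{instruction}", "{input}", "{completion}"):
        if ph not in template:
            raise ConfigError(f"prompt template is missing the {ph} placeholder")
    head, _, tail = template.partition("{completion}")
    prompt = head.replace("{instruction}", instruction).replace(
        "{input}", rec.procedure_text
    )
    completion = rec.record.to_json() + tail.replace("{instruction}", instruction)
    return PromptExample(
        prompt=prompt,
        completion=completion,
        token_count=tokenizer(prompt + completion),
        source_id=rec.source_id,
    )


def dedupe(
    examples: Sequence[PromptExample],
    conflicts: list[tuple[str, str]] | None = None,
) -> list[PromptExample]:
    """Keep the first example per prompt, preserving order.

    The dedup key is the prompt string only; a repeated prompt carrying a
    different completion is a conflict, logged (and collected when a
    ``conflicts`` list is supplied) but still dropped.
    """
    seen: dict[str, str] = {}
    out: list[PromptExample] = []
    for ex in examples:
        if ex.prompt not in seen:
            seen[ex.prompt] = ex.completion
            out.append(ex)
        elif seen[ex.prompt] != ex.completion:
            logger.warning("duplicate prompt with conflicting completion dropped")
            if conflicts is not None:
                conflicts.append((ex.prompt, ex.completion))
    return out


def token_filter(
    examples: Sequence[PromptExample],
    tokenizer: Callable[[str], int] | None = None,
    limit: int = 2048,
) -> tuple[list[PromptExample], list[PromptExample]]:
    """Keep examples whose token count is within the (inclusive) limit."""
    kept: list[PromptExample] = []
    dropped: list[PromptExample] = []
    for ex in examples:
        n = tokenizer(ex.prompt + ex.completion) if tokenizer else ex.token_count
        ex.token_count = n
        (kept if n <= limit else dropped).append(ex)
    return kept, dropped


SPLITS = ("train", "validation", "test")


def split(
    examples: Sequence[PromptExample],
    ratios: Sequence[float] = (8, 1, 1),
    seed: int = 0,
) -> list[PromptExample]:
    """Random train/validation/test split by seeded shuffle and
    largest-remainder apportionment; disjoint, exhaustive, reproducible."""
    if len(ratios) != 3 or any(r < 0 for r in ratios) or sum(ratios) <= 0:
        raise ConfigError(f"bad split ratios {ratios!r}")
    n = len(examples)
    n_parts = sum(1 for r in ratios if r > 0)
    if n < n_parts:
        raise ConfigError(f"cannot split {n} examples into {n_parts} non-empty parts")
    total = float(sum(ratios))
    quotas = [n * r / total for r in ratios]
    sizes = [int(q) for q in quotas]
    remainders = sorted(
        range(3), key=lambda i: (-(quotas[i] - sizes[i]), i)
    )
    for i in remainders[: n - sum(sizes)]:
        sizes[i] += 1

    order = list(range(n))
    random.Random(seed).shuffle(order)
    assigned = list(examples)
    pos = 0
    for name, size in zip(SPLITS, sizes):
        for idx in order[pos : pos + size]:
            assigned[idx].split = name
        pos += size
    return list(assigned)


def prep_report(
    n_in: int,
    n_admitted: int,
    n_unique: int,
    n_within_limit: int,
    seed: int | None = None,
    metadata: dict | None = None,
) -> PrepReport:
    """Stage counts with the retention percentage of the length filter,
    ``100 * n_within_limit / n_unique`` at one decimal, half-up."""
    counts = (n_in, n_admitted, n_unique, n_within_limit)
    if any(c < 0 for c in counts):
        raise ConfigError("stage counts must be non-negative")
    if not (n_in >= n_admitted >= n_unique >= n_within_limit):
        raise ConfigError(f"stage counts must be non-increasing, got {counts}")
    return PrepReport(
        n_in=n_in,
        n_admitted=n_admitted,
        n_unique=n_unique,
        n_within_limit=n_within_limit,
        retention_pct=pct(n_within_limit, n_unique),
        seed=seed,
        metadata=metadata or {},
    )
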