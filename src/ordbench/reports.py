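"""Report arithmetic and rendering: percentage formatting, summary tables,
and the adaption-prompt parameter-count helper."""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .evaluate import EvalResult, LeafTally, MessageTally, aggregate_results

__all__ = [
    "pct",
    "format_pct",
    "adapter_param_count",
    "format_millions",
    "aggregate_report",
    "render_message_table",
    "render_leaf_table",
]

UNDEFINED = "n/a"  # marker for a percentage over a zero denominator


def pct(count: int, total: int, decimals: int = 1) -> float | None:
    """``100 * count / total`` rounded half-up to ``decimals``; None if total=0."""
    if total == 0:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


def format_pct(value: float | None, decimals: int = 1) -> str:
    if value is None:
        return UNDEFINED
    return f"{value:.{decimals}f}%"


def adapter_param_count(k: int, layers: int, embed_dim: int) -> int:
    """Trainable parameters of a learnable-prefix adapter: prompt length x
    adapted layers x token embedding dimension."""
    for name, v in (("k", k), ("layers", layers), ("embed_dim", embed_dim)):
        if not isinstance(v, int) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    return k * layers * embed_dim


def format_millions(n: int, decimals: int = 1) -> str:
    q = Decimal(1).scaleb(-decimals)
    m = (Decimal(n) / Decimal(1_000_000)).quantize(q, rounding=ROUND_HALF_UP)
    return f"{m} million"


def _tally_row(t: MessageTally | LeafTally) -> dict:
    total = t.total
    return {
        "accurate": t.accurate,
        "removal": t.removal,
        "addition": t.addition,
        "alteration": t.alteration,
        "total": total,
        "accurate_pct": pct(t.accurate, total),
        "removal_pct": pct(t.removal, total),
        # additions are reported over the same ground-truth denominator
        "addition_pct": pct(t.addition, total),
        "alteration_pct": pct(t.alteration, total),
    }


MESSAGE_ORDER = ("Compound", "ProductCompound", "ReactionConditions", "ReactionWorkup")
LEAF_ORDER = ("identifiers", "amount", "reaction_role", "condition", "workup", "other")


def aggregate_report(results: Sequence[EvalResult] | EvalResult) -> dict:
    """Corpus-level report: summed tallies, percentages at one decimal
    (half-up), lenient variants where defined, and the unweighted mean of
    per-type accuracies (lenient where available)."""
    agg = results if isinstance(results, EvalResult) else aggregate_results(results)

    message_level: dict[str, dict] = {}
    for mtype in MESSAGE_ORDER:
        if mtype not in agg.message_tallies:
            continue
        row = _tally_row(agg.message_tallies[mtype])
        if mtype in agg.lenient_tallies:
            lt = agg.lenient_tallies[mtype]
            row["lenient_accurate"] = lt.accurate
            row["lenient_alteration"] = lt.alteration
            row["lenient_accurate_pct"] = pct(lt.accurate, lt.total)
            row["lenient_alteration_pct"] = pct(lt.alteration, lt.total)
        message_level[mtype] = row

    leaf_level: dict[str, dict] = {}
    for ft in LEAF_ORDER:
        if ft in agg.leaf_tallies:
            leaf_level[ft] = _tally_row(agg.leaf_tallies[ft])

    def _best_acc(row: dict) -> float | None:
        return row.get("lenient_accurate_pct", row["accurate_pct"])

    msg_accs = [a for a in (_best_acc(r) for r in message_level.values()) if a is not None]
    leaf_accs = [r["accurate_pct"] for r in leaf_level.values() if r["accurate_pct"] is not None]

    def _mean(vals: list[float]) -> float | None:
        if not vals:
            return None
        q = Decimal("0.01")
        return float(
            (sum(Decimal(str(v)) for v in vals) / len(vals)).quantize(
                q, rounding=ROUND_HALF_UP
            )
        )

    return {
        "message_level": message_level,
        "leaf_level": leaf_level,
        "message_accuracy_mean_pct": _mean(msg_accs),
        "leaf_accuracy_mean_pct": _mean(leaf_accs),
    }


def _render_table(rows: dict[str, dict], key_header: str) -> str:
    cols = ("accurate", "removal", "addition", "alteration", "total")
    lines = [key_header + "\t" + "\t".join(c.capitalize() for c in cols)]
    for name, row in rows.items():
        cells = []
        for c in cols[:-1]:
            p = format_pct(row[f"{c}_pct"])
            cells.append(f"{row[c]} ({p})")
        cells.append(str(row["total"]))
        lines.append(name + "\t" + "\t".join(cells))
        if "lenient_accurate" in row:
            la = f'{row["lenient_accurate"]} ({format_pct(row["lenient_accurate_pct"])})*'
            lt = f'{row["lenient_alteration"]} ({format_pct(row["lenient_alteration_pct"])})*'
            lines.append(name + " (lenient)\t" + la + "\t\t\t" + lt + "\t")
    return "\n".join(lines) + "\n"


def render_message_table(report: dict) -> str:
    return _render_table(report["message_level"], "Message type")


def render_leaf_table(report: dict) -> str:
    return _render_table(report["leaf_level"], "Field type")


def report_to_json(report: dict, *, indent: int = 2) -> str:
    return json.dumps(report, indent=indent, ensure_ascii=False)
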