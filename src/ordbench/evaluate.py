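"""Message- and leaf-level scoring of extracted reaction records.

Two granularities are scored, both built on a single edit distance for
nested objects:

* **Message level** — for each message type (input Compound, ProductCompound,
  ReactionConditions, ReactionWorkup), how many ground-truth messages were
  extracted accurately, or erroneously removed or altered, and how many
  extra messages were added?
* **Leaf level** — the same four failure modes counted per scalar leaf
  field, bucketed by field type (identifiers, amount, reaction role,
  condition, workup, other).

The distance between two messages is the number of leaf paths present in
exactly one of them plus the number of shared paths holding unequal values;
repeated sub-lists are first aligned by the minimum-cost pairing of their
items, recursively.  The distance of any message to the empty message is
its populated leaf count.  When two lists of messages are compared, the
shorter is padded with empty messages and a bijection minimizing the total
distance is found (Hungarian method); the bijection determines the failure
mode of every pair:

* ``ACCURATE``  — matched at distance zero,
* ``ALTERATION`` — matched at positive distance,
* ``REMOVAL``   — ground-truth message matched to a pad,
* ``ADDITION``  — predicted message matched to a pad.

A message counted ACCURATE therefore has zero leaf-level failures, making
the message metric strictly more stringent than the leaf metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Callable, Iterator, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .schema import (
    MessageNode,
    Path,
    count_leaves,
    iter_leaves,
    path_pattern,
    render_path,
)

__all__ = [
    "EMPTY",
    "Mode",
    "MatchedPair",
    "MessageTally",
    "LeafTally",
    "EvalResult",
    "node_distance",
    "match_messages",
    "classify_messages",
    "classify_leaves",
    "lenient_equal_product",
    "lenient_equal_compound",
    "evaluate_reaction",
    "aggregate_results",
    "default_field_type",
]

EMPTY = None  # the empty message used for padding


class Mode(str, Enum):
    ACCURATE = "ACCURATE"
    REMOVAL = "REMOVAL"
    ADDITION = "ADDITION"
    ALTERATION = "ALTERATION"


def _scalar_equal(a: Any, b: Any) -> bool:
    """Numbers compare numerically (5 == 5.0); strings after trimming."""
    a_num = isinstance(a, (int, float)) and not isinstance(a, bool)
    b_num = isinstance(b, (int, float)) and not isinstance(b, bool)
    if a_num and b_num:
        return float(a) == float(b)
    if isinstance(a, str) and isinstance(b, str):
        return a.strip() == b.strip()
    return a == b


def _as_data(x: Any) -> Any:
    return x.data if isinstance(x, MessageNode) else x


def _dist(a: Any, b: Any) -> int:
    if a is None and b is None:
        return 0
    if a is None:
        return count_leaves(b)
    if b is None:
        return count_leaves(a)
    if isinstance(a, dict) and isinstance(b, dict):
        total = 0
        for k in a.keys() | b.keys():
            total += _dist(a.get(k), b.get(k))
        return total
    if isinstance(a, list) and isinstance(b, list):
        n = max(len(a), len(b))
        pa = list(a) + [None] * (n - len(a))
        pb = list(b) + [None] * (n - len(b))
        cost = np.array([[_dist(x, y) for y in pb] for x in pa], dtype=float)
        rows, cols = linear_sum_assignment(cost)
        return int(cost[rows, cols].sum())
    if isinstance(a, (dict, list)) or isinstance(b, (dict, list)):
        # shape mismatch: nothing is shared
        return count_leaves(a) + count_leaves(b)
    return 0 if _scalar_equal(a, b) else 1


def node_distance(a: MessageNode | None, b: MessageNode | None) -> int:
    """Edit distance between two messages of the same type (or EMPTY).

    Symmetric, non-negative, zero iff the populated leaf sets are identical.
    """
    if a is not None and b is not None and isinstance(a, MessageNode) and isinstance(b, MessageNode):
        if a.message_type != b.message_type:
            raise TypeError(
                f"cannot compare {a.message_type} with {b.message_type}"
            )
    return _dist(_as_data(a), _as_data(b))


@dataclass
class MatchedPair:
    gt: Any  # message data (dict) or EMPTY
    pred: Any
    distance: int
    mode: Mode
    gt_index: int | None = None
    pred_index: int | None = None


def _lex_assignment(cost: np.ndarray) -> list[int]:
    """Minimum-cost assignment; ties broken lexicographically by (row, col).

    Returns ``col_of_row`` such that row i is paired with col_of_row[i].
    """
    n = cost.shape[0]
    rows, cols = linear_sum_assignment(cost)
    best = cost[rows, cols].sum()
    col_of_row: list[int] = []
    free_cols = list(range(n))
    spent = 0.0
    for i in range(n):
        chosen = None
        for j in free_cols:
            rest_rows = [r for r in range(i + 1, n)]
            rest_cols = [c for c in free_cols if c != j]
            if rest_rows:
                sub = cost[np.ix_(rest_rows, rest_cols)]
                rr, cc = linear_sum_assignment(sub)
                rest = sub[rr, cc].sum()
            else:
                rest = 0.0
            if spent + cost[i, j] + rest == best:
                chosen = j
                break
        assert chosen is not None
        col_of_row.append(chosen)
        free_cols.remove(chosen)
        spent += cost[i, chosen]
    return col_of_row


def match_messages(
    gt_list: Sequence[Any], pred_list: Sequence[Any]
) -> list[MatchedPair]:
    """Optimal bijective matching between two lists of same-type messages.

    The shorter list is padded with empty messages so both have equal size;
    the bijection minimizing the summed pair distances is returned.  Only
    the shorter side carries pads, so a pad never pairs with a pad.
    """
    gt = [_as_data(x) for x in gt_list]
    pred = [_as_data(x) for x in pred_list]
    n = max(len(gt), len(pred))
    if n == 0:
        return []
    pg = gt + [None] * (n - len(gt))
    pp = pred + [None] * (n - len(pred))
    cost = np.array([[_dist(a, b) for b in pp] for a in pg], dtype=float)
    col_of_row = _lex_assignment(cost)
    pairs: list[MatchedPair] = []
    for i, j in enumerate(col_of_row):
        a, b = pg[i], pp[j]
        d = int(cost[i, j])
        if i >= len(gt) and j >= len(pred):
            continue  # unreachable: pads exist on one side only
        if i >= len(gt):
            mode = Mode.ADDITION
        elif j >= len(pred):
            mode = Mode.REMOVAL
        elif d == 0:
            mode = Mode.ACCURATE
        else:
            mode = Mode.ALTERATION
        pairs.append(
            MatchedPair(
                gt=a,
                pred=b,
                distance=d,
                mode=mode,
                gt_index=i if i < len(gt) else None,
                pred_index=j if j < len(pred) else None,
            )
        )
    return pairs


@dataclass
class MessageTally:
    message_type: str
    accurate: int = 0
    removal: int = 0
    addition: int = 0
    alteration: int = 0

    @property
    def total(self) -> int:
        # additions are extra to ground truth and excluded from the total
        return self.accurate + self.removal + self.alteration

    def add(self, other: "MessageTally") -> None:
        self.accurate += other.accurate
        self.removal += other.removal
        self.addition += other.addition
        self.alteration += other.alteration


@dataclass
class LeafTally:
    field_type: str
    accurate: int = 0
    removal: int = 0
    addition: int = 0
    alteration: int = 0

    @property
    def total(self) -> int:
        return self.accurate + self.removal + self.alteration

    def add(self, other: "LeafTally") -> None:
        self.accurate += other.accurate
        self.removal += other.removal
        self.addition += other.addition
        self.alteration += other.alteration


def classify_messages(
    pairs: Sequence[MatchedPair], message_type: str = ""
) -> MessageTally:
    t = MessageTally(message_type=message_type)
    for p in pairs:
        if p.mode is Mode.ACCURATE:
            t.accurate += 1
        elif p.mode is Mode.REMOVAL:
            t.removal += 1
        elif p.mode is Mode.ADDITION:
            t.addition += 1
        else:
            t.alteration += 1
    return t


# ---------------------------------------------------------------------------
# Leaf-level diffing.  Mirrors the recursive list alignment used by the
# distance so leaf attributions are consistent with the distance value.
# ---------------------------------------------------------------------------


def _leaf_diff(a: Any, b: Any, prefix: Path) -> Iterator[tuple[Path, Mode]]:
    if a is None and b is None:
        return
    if a is None:
        for p, _ in iter_leaves(b, prefix):
            yield p, Mode.ADDITION
        return
    if b is None:
        for p, _ in iter_leaves(a, prefix):
            yield p, Mode.REMOVAL
        return
    if isinstance(a, dict) and isinstance(b, dict):
        for k in list(a.keys()) + [k for k in b.keys() if k not in a]:
            yield from _leaf_diff(a.get(k), b.get(k), prefix + (("f", k),))
        return
    if isinstance(a, list) and isinstance(b, list):
        n = max(len(a), len(b))
        pa = list(a) + [None] * (n - len(a))
        pb = list(b) + [None] * (n - len(b))
        cost = np.array([[_dist(x, y) for y in pb] for x in pa], dtype=float)
        col_of_row = _lex_assignment(cost)
        for i, j in enumerate(col_of_row):
            yield from _leaf_diff(pa[i], pb[j], prefix + (("i", i),))
        return
    if isinstance(a, (dict, list)) or isinstance(b, (dict, list)):
        for p, _ in iter_leaves(a, prefix):
            yield p, Mode.REMOVAL
        for p, _ in iter_leaves(b, prefix):
            yield p, Mode.ADDITION
        return
    yield prefix, (Mode.ACCURATE if _scalar_equal(a, b) else Mode.ALTERATION)


FIELD_TYPES = ("identifiers", "amount", "reaction_role", "condition", "workup", "other")


def default_field_type(message_type: str, leaf_pattern: str) -> str:
    """Bucket a leaf by field type, given its message-type context."""
    if message_type == "ReactionConditions":
        return "condition"
    if message_type == "ReactionWorkup":
        return "workup"
    if "identifiers" in leaf_pattern:
        return "identifiers"
    if "amount" in leaf_pattern:
        return "amount"
    if leaf_pattern.split(".")[-1] == "reaction_role":
        return "reaction_role"
    return "other"


def classify_leaves(
    pairs: Sequence[MatchedPair],
    message_type: str,
    field_type_map: Callable[[str, str], str] = default_field_type,
) -> dict[str, LeafTally]:
    """Leaf-level failure modes, bucketed by field type.

    A REMOVAL message contributes every one of its leaves as a removal, an
    ADDITION message every leaf as an addition; matched pairs are diffed
    leaf by leaf under the same recursive list alignment as the distance.
    """
    out: dict[str, LeafTally] = {}

    def bump(pattern: str, mode: Mode) -> None:
        ft = field_type_map(message_type, pattern)
        if ft not in FIELD_TYPES:
            ft = "other"
        tally = out.setdefault(ft, LeafTally(field_type=ft))
        if mode is Mode.ACCURATE:
            tally.accurate += 1
        elif mode is Mode.REMOVAL:
            tally.removal += 1
        elif mode is Mode.ADDITION:
            tally.addition += 1
        else:
            tally.alteration += 1

    for p in pairs:
        if p.mode is Mode.REMOVAL:
            for path, _ in iter_leaves(p.gt):
                bump(path_pattern(path), Mode.REMOVAL)
        elif p.mode is Mode.ADDITION:
            for path, _ in iter_leaves(p.pred):
                bump(path_pattern(path), Mode.ADDITION)
        else:
            for path, mode in _leaf_diff(p.gt, p.pred, ()):
                bump(path_pattern(path), mode)
    return out


# ---------------------------------------------------------------------------
# Lenient equivalence
# ---------------------------------------------------------------------------


def _identifier_multiset(data: dict) -> tuple:
    ids = data.get("identifiers") or []
    return tuple(
        sorted(
            (str(i.get("type", "")).strip(), str(i.get("value", "")).strip())
            for i in ids
            if isinstance(i, dict)
        )
    )


def _amount_leaves(data: dict) -> tuple:
    out = []
    for path, value in iter_leaves(data):
        pat = path_pattern(path)
        if "amount" in pat:
            out.append((pat, value if not isinstance(value, str) else value.strip()))
    return tuple(sorted(out, key=repr))


def lenient_equal_product(a: Any, b: Any) -> bool:
    """Two product messages are leniently identical when their identifier
    multisets and all amount-bearing leaves agree; derived fields such as
    calculated yields, texture, and isolated color are ignored."""
    da, db = _as_data(a), _as_data(b)
    if da is None or db is None:
        return False
    return (
        _identifier_multiset(da) == _identifier_multiset(db)
        and _amount_leaves(da) == _amount_leaves(db)
    )


def _without_role(data: dict) -> dict:
    return {k: v for k, v in data.items() if k != "reaction_role"}


def lenient_equal_compound(a: Any, b: Any) -> bool:
    """Input-compound equivalence ignoring the (inferred) reaction role."""
    da, db = _as_data(a), _as_data(b)
    if da is None or db is None:
        return False
    return _dist(_without_role(da), _without_role(db)) == 0


# ---------------------------------------------------------------------------
# Whole-reaction evaluation
# ---------------------------------------------------------------------------

MESSAGE_TYPES = ("Compound", "ProductCompound", "ReactionConditions", "ReactionWorkup")

_LENIENT_RULES: dict[str, Callable[[Any, Any], bool]] = {
    "Compound": lenient_equal_compound,
    "ProductCompound": lenient_equal_product,
}


def _input_compounds(data: dict | None) -> list[dict]:
    if not data:
        return []
    out = []
    for inp in (data.get("inputs") or {}).values():
        out.extend(c for c in (inp.get("components") or []) if isinstance(c, dict))
    return out


def _products(data: dict | None) -> list[dict]:
    if not data:
        return []
    out = []
    for outcome in data.get("outcomes") or []:
        out.extend(p for p in (outcome.get("products") or []) if isinstance(p, dict))
    return out


@dataclass
class EvalResult:
    message_tallies: dict[str, MessageTally] = field(default_factory=dict)
    lenient_tallies: dict[str, MessageTally] = field(default_factory=dict)
    leaf_tallies: dict[str, LeafTally] = field(default_factory=dict)
    pairs: dict[str, list[MatchedPair]] = field(default_factory=dict)


def _lenient_upgrade(
    pairs: Sequence[MatchedPair], message_type: str, rule: Callable[[Any, Any], bool]
) -> MessageTally:
    t = MessageTally(message_type=message_type)
    for p in pairs:
        mode = p.mode
        if mode is Mode.ALTERATION and rule(p.gt, p.pred):
            mode = Mode.ACCURATE
        if mode is Mode.ACCURATE:
            t.accurate += 1
        elif mode is Mode.REMOVAL:
            t.removal += 1
        elif mode is Mode.ADDITION:
            t.addition += 1
        else:
            t.alteration += 1
    return t


def evaluate_reaction(
    gt: MessageNode, pred: MessageNode | None
) -> EvalResult:
    """Score one predicted reaction record against its ground truth.

    Input compounds are pooled across all reaction inputs, products across
    all outcomes; workups are matched as an ordered list; the reaction
    conditions are compared as one single message, so only ACCURATE and
    ALTERATION apply to them.  An unparseable prediction counts as the
    removal of every ground-truth message.
    """
    gt_data = gt.data
    pred_data = pred.data if pred is not None else None
    res = EvalResult()

    groups: dict[str, tuple[list, list]] = {
        "Compound": (_input_compounds(gt_data), _input_compounds(pred_data)),
        "ProductCompound": (_products(gt_data), _products(pred_data)),
        "ReactionWorkup": (
            list((gt_data or {}).get("workups") or []),
            list((pred_data or {}).get("workups") or []),
        ),
    }
    for mtype, (g, p) in groups.items():
        pairs = match_messages(g, p)
        res.pairs[mtype] = pairs
        res.message_tallies[mtype] = classify_messages(pairs, mtype)
        if mtype in _LENIENT_RULES:
            res.lenient_tallies[mtype] = _lenient_upgrade(
                pairs, mtype, _LENIENT_RULES[mtype]
            )
        for ft, tally in classify_leaves(pairs, mtype).items():
            res.leaf_tallies.setdefault(ft, LeafTally(field_type=ft)).add(tally)

    # conditions: a single message, never a list
    g_cond = (gt_data or {}).get("conditions")
    p_cond = (pred_data or {}).get("conditions")
    if g_cond is not None:
        d = _dist(g_cond, p_cond)
        mode = Mode.ACCURATE if d == 0 else Mode.ALTERATION
        pair = MatchedPair(gt=g_cond, pred=p_cond, distance=d, mode=mode,
                           gt_index=0, pred_index=0 if p_cond is not None else None)
        res.pairs["ReactionConditions"] = [pair]
        res.message_tallies["ReactionConditions"] = classify_messages(
            [pair], "ReactionConditions"
        )
        for path, mode in _leaf_diff(g_cond, p_cond, ()):
            ft = "condition"
            tally = res.leaf_tallies.setdefault(ft, LeafTally(field_type=ft))
            if mode is Mode.ACCURATE:
                tally.accurate += 1
            elif mode is Mode.REMOVAL:
                tally.removal += 1
            elif mode is Mode.ADDITION:
                tally.addition += 1
            else:
                tally.alteration += 1
    elif p_cond is not None:
        # nothing in ground truth: every predicted condition leaf is an addition
        tally = res.leaf_tallies.setdefault("condition", LeafTally(field_type="condition"))
        tally.addition += count_leaves(p_cond)
        res.message_tallies.setdefault(
            "ReactionConditions", MessageTally(message_type="ReactionConditions")
        )
    return res


def aggregate_results(results: Sequence[EvalResult]) -> EvalResult:
    """Sum per-reaction tallies into corpus-level tallies."""
    agg = EvalResult()
    for r in results:
        for mtype, t in r.message_tallies.items():
            agg.message_tallies.setdefault(mtype, MessageTally(message_type=mtype)).add(t)
        for mtype, t in r.lenient_tallies.items():
            agg.lenient_tallies.setdefault(mtype, MessageTally(message_type=mtype)).add(t)
        for ft, t in r.leaf_tallies.items():
            agg.leaf_tallies.setdefault(ft, LeafTally(field_type=ft)).add(t)
    return agg
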