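"""Compound-name recognition scoring and reaction-role classification.

Name recognition treats the multiset of NAME identifiers in a record —
including referencing tokens such as "desired product" or "compound 322" —
as the extracted entity set and scores it against ground truth by a
minimum-cost matching under normalized string edit distance.  Role
classification scores the inferred reaction_role of every ground-truth
input compound (REACTANT / SOLVENT / CATALYST in this corpus); a compound
absent from the prediction is MISSING, one extracted under a wrong name is
ERROR.  A popularity baseline predicts each compound's most frequent
training-set role, breaking ties and unseen names uniformly at random.
"""

from __future__ import annotations

import random
import re
import zlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import edlib
import numpy as np
from scipy.optimize import linear_sum_assignment

from .evaluate import Mode, match_messages
from .schema import MessageNode

__all__ = [
    "ROLES",
    "CONFUSION_COLUMNS",
    "NameTally",
    "RoleFrequencyTable",
    "RoleConfusion",
    "normalize_name",
    "extract_names",
    "compare_names",
    "build_popularity_table",
    "popularity_predict",
    "role_confusion",
    "macro_f1",
]

ROLES = ("REACTANT", "SOLVENT", "CATALYST")
CONFUSION_COLUMNS = ROLES + ("MISSING", "ERROR")

_PAD_EPS = 1e-6  # pad cost 1 + eps: equally bad real pairings beat pads


def normalize_name(name: str) -> str:
    """Trim and collapse internal whitespace; case is preserved because
    chemical names are case-meaningful (pH vs PH, NaH vs nah)."""
    return re.sub(r"\s+", " ", name).strip()


def _compound_lists(data: dict | None) -> Iterable[dict]:
    if not data:
        return
    for inp in (data.get("inputs") or {}).values():
        yield from (c for c in (inp.get("components") or []) if isinstance(c, dict))
    for outcome in data.get("outcomes") or []:
        yield from (p for p in (outcome.get("products") or []) if isinstance(p, dict))


def compound_name(compound: dict) -> str | None:
    for ident in compound.get("identifiers") or []:
        if isinstance(ident, dict) and ident.get("type") == "NAME":
            v = ident.get("value")
            if isinstance(v, str):
                return normalize_name(v)
    return None


def extract_names(record: MessageNode | dict | None) -> list[str]:
    """All NAME identifier values of input compounds and products."""
    data = record.data if isinstance(record, MessageNode) else record
    out: list[str] = []
    for comp in _compound_lists(data):
        for ident in comp.get("identifiers") or []:
            if isinstance(ident, dict) and ident.get("type") == "NAME":
                v = ident.get("value")
                if isinstance(v, str):
                    out.append(normalize_name(v))
    return out


@dataclass
class NameTally:
    accurate: int = 0
    removal: int = 0
    addition: int = 0
    alteration: int = 0

    @property
    def total(self) -> int:
        return self.accurate + self.removal + self.alteration

    def add(self, other: "NameTally") -> None:
        self.accurate += other.accurate
        self.removal += other.removal
        self.addition += other.addition
        self.alteration += other.alteration


def _name_cost(a: str, b: str) -> float:
    if a == b:
        return 0.0
    d = edlib.align(a, b)["editDistance"]
    return d / max(len(a), len(b), 1)


def compare_names(gt: Sequence[str], pred: Sequence[str]) -> NameTally:
    """Score predicted names against ground-truth names.

    The shorter multiset is padded; pairs are found by minimum total cost
    where the cost of two names is their normalized edit distance in
    [0, 1] and the cost of pairing with a pad is 1.  Identical pairs are
    accurate, matched non-identical pairs are alterations, unmatched
    ground-truth names removals, unmatched predictions additions.
    """
    gt = [normalize_name(x) for x in gt]
    pred = [normalize_name(x) for x in pred]
    t = NameTally()
    n = max(len(gt), len(pred))
    if n == 0:
        return t
    cost = np.full((n, n), 1.0 + _PAD_EPS)
    for i, a in enumerate(gt):
        for j, b in enumerate(pred):
            cost[i, j] = _name_cost(a, b)
    rows, cols = linear_sum_assignment(cost)
    for i, j in zip(rows, cols):
        if i >= len(gt) and j >= len(pred):
            continue
        if i >= len(gt):
            t.addition += 1
        elif j >= len(pred):
            t.removal += 1
        elif gt[i] == pred[j]:
            t.accurate += 1
        else:
            t.alteration += 1
    return t


# ---------------------------------------------------------------------------
# Popularity baseline
# ---------------------------------------------------------------------------

RoleFrequencyTable = dict[str, Counter]


def build_popularity_table(training: Iterable[MessageNode | dict]) -> RoleFrequencyTable:
    """Accumulate (compound name, reaction role) counts over a training
    corpus; input compounds only, roles restricted to the three classes."""
    table: RoleFrequencyTable = {}
    for rec in training:
        data = rec.data if isinstance(rec, MessageNode) else rec
        if not data:
            continue
        for inp in (data.get("inputs") or {}).values():
            for comp in inp.get("components") or []:
                if not isinstance(comp, dict):
                    continue
                role = comp.get("reaction_role")
                name = compound_name(comp)
                if name is None or role not in ROLES:
                    continue
                table.setdefault(name, Counter())[role] += 1
    return table


def _rng_for(name: str, rng: random.Random | int) -> random.Random:
    if isinstance(rng, random.Random):
        return rng
    # stable per-name stream: independent of call order, stable across runs
    return random.Random(zlib.crc32(name.encode("utf-8")) ^ (rng & 0x7FFFFFFF))


def popularity_predict(
    name: str, table: RoleFrequencyTable, rng: random.Random | int
) -> str:
    """Most frequent training role of the compound; ties and unseen names
    are resolved uniformly at random (deterministic when ``rng`` is an
    integer seed: the draw depends only on name and seed)."""
    name = normalize_name(name)
    counts = table.get(name)
    if not counts:
        candidates = list(ROLES)
    else:
        top = max(counts.values())
        candidates = [r for r in ROLES if counts.get(r, 0) == top]
    if len(candidates) == 1:
        return candidates[0]
    return _rng_for(name, rng).choice(candidates)


# ---------------------------------------------------------------------------
# Role confusion matrix and macro F1
# ---------------------------------------------------------------------------


@dataclass
class RoleConfusion:
    counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            r: {c: 0 for c in CONFUSION_COLUMNS} for r in ROLES
        }
    )

    def bump(self, true_role: str, predicted: str) -> None:
        self.counts[true_role][predicted] += 1

    def row_total(self, true_role: str) -> int:
        return sum(self.counts[true_role].values())

    def normalized(self) -> dict[str, dict[str, float | None]]:
        """Row-normalized percentages: each row is divided by the number of
        true instances of that role."""
        from .reports import pct

        out: dict[str, dict[str, float | None]] = {}
        for r in ROLES:
            total = self.row_total(r)
            out[r] = {c: pct(v, total) for c, v in self.counts[r].items()}
        return out

    def add(self, other: "RoleConfusion") -> None:
        for r in ROLES:
            for c in CONFUSION_COLUMNS:
                self.counts[r][c] += other.counts[r][c]


def _gt_input_compounds(data: dict | None) -> list[dict]:
    out = []
    for inp in ((data or {}).get("inputs") or {}).values():
        out.extend(c for c in (inp.get("components") or []) if isinstance(c, dict))
    return out


def role_confusion(
    gt_records: Sequence[MessageNode | dict],
    pred_records: Sequence[MessageNode | dict | None],
    predicted_role: Any = None,
) -> RoleConfusion:
    """Confusion matrix of reaction-role assignment over paired records.

    Ground-truth and predicted input compounds are paired by the same
    optimal matching used for message-level scoring.  For each ground-truth
    compound with a classifiable role: an unmatched compound is MISSING; a
    matched compound under a different (or absent) name is ERROR; otherwise
    the predicted role is tallied against the true role.  When
    ``predicted_role`` is given (a callable ``name -> role``), it overrides
    the role stored in the matched prediction — this is how the popularity
    baseline is scored.
    """
    cm = RoleConfusion()
    if len(gt_records) != len(pred_records):
        raise ValueError("ground-truth and prediction lists must be paired")
    for gt, pred in zip(gt_records, pred_records):
        g_data = gt.data if isinstance(gt, MessageNode) else gt
        p_data = pred.data if isinstance(pred, MessageNode) else pred
        pairs = match_messages(_gt_input_compounds(g_data), _gt_input_compounds(p_data))
        for pair in pairs:
            if pair.gt is None:
                continue  # additions carry no true role
            true_role = pair.gt.get("reaction_role")
            if true_role not in ROLES:
                continue
            g_name = compound_name(pair.gt)
            if pair.mode is Mode.REMOVAL or pair.pred is None:
                cm.bump(true_role, "MISSING")
                continue
            p_name = compound_name(pair.pred)
            if g_name != p_name:
                cm.bump(true_role, "ERROR")
                continue
            if predicted_role is not None:
                pred_role = predicted_role(p_name)
            else:
                pred_role = pair.pred.get("reaction_role")
            if pred_role in ROLES:
                cm.bump(true_role, pred_role)
            else:
                # present under the right name but with a missing/invalid
                # role: the extraction is wrong, not absent
                cm.bump(true_role, "ERROR")
    return cm


def macro_f1(cm: RoleConfusion) -> float | None:
    """Unweighted mean F1 over the three role classes.

    MISSING and ERROR cells are false negatives of the true role and false
    positives of no role.  A class with neither true nor predicted
    instances contributes 0.  Undefined (None) only for an all-empty matrix.
    """
    if all(cm.row_total(r) == 0 for r in ROLES):
        return None
    f1s = []
    for r in ROLES:
        tp = cm.counts[r][r]
        fn = cm.row_total(r) - tp
        fp = sum(cm.counts[r2][r] for r2 in ROLES if r2 != r)
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return sum(f1s) / len(f1s)
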