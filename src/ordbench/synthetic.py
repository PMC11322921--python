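"""Synthetic USPTO-style (procedure text, reaction record) pairs with a
perturbation engine that injects logged corruptions.

The generator emulates the register of patent procedure paragraphs ("A
solution of X (a g) in Y (b mL) was stirred at T °C ... to give P (c g,
d%)"): every reaction has 1-4 inputs each holding named, quantified
compounds with reaction roles, a temperature condition, 1-5 typed workups,
and one product with a name and an integer yield.  In the default
"consistent" mode every compound name and the integer yield appear
verbatim in the rendered text, so implicit-information scrubbing removes
nothing; an omit-product-name probability exercises the scrubbing rule.

The perturbation engine corrupts a copy of a record with a requested
number of message additions, removals, and single-leaf alterations per
message type and returns the log of what it did — the known-answer oracle
for metric-recovery tests.  Alterations always write fresh values that
collide with nothing else in the record, and generated compounds differ
pairwise in at least two leaves, so the optimal matching stays
unambiguous: each corrupted message remains closer to its origin than to
any other message.  Because list matching pads only the shorter list,
additions and removals of the same message type within one record cancel
into alterations; spec sampling therefore applies adds or removals per
type, never both (the "unambiguity guarantee").
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field as dc_field
from typing import Sequence

from .prep import CorpusRecord
from .schema import MessageNode, SchemaSpec

__all__ = [
    "GenConfig",
    "PerturbEntry",
    "PerturbationLog",
    "PerturbSpec",
    "gen_reaction",
    "gen_corpus",
    "perturb",
    "sample_perturb_spec",
    "DEFAULT_ROLE_FREQ",
]

_PREFIXES = (
    "methyl", "ethyl", "4-chloro", "2-bromo", "3-nitro", "N-benzyl",
    "4-methoxy", "2-fluoro", "tert-butyl", "phenyl", "3-amino", "2,6-dimethyl",
)
_CORES = (
    "benzoate", "aniline", "pyridine", "phenol", "acetamide", "indole",
    "piperidine", "benzaldehyde", "quinoline", "imidazole", "benzonitrile",
    "cyclohexanone",
)
_SOLVENTS = (
    "tetrahydrofuran", "dichloromethane", "ethanol", "methanol", "toluene",
    "N,N-dimethylformamide", "ethyl acetate", "acetonitrile", "1,4-dioxane",
    "diethyl ether",
)
_CATALYSTS = (
    "palladium on carbon", "palladium acetate", "p-toluenesulfonic acid",
    "copper(I) iodide", "sulfuric acid", "4-dimethylaminopyridine",
)
_WORKUP_TYPES = (
    "FILTRATION", "EXTRACTION", "WASH", "CONCENTRATION", "DRY_WITH_MATERIAL",
    "RECRYSTALLIZATION", "DISTILLATION", "CHROMATOGRAPHY",
)
_WORKUP_SENTENCES = {
    "FILTRATION": "The mixture was filtered through a pad of celite.",
    "EXTRACTION": "The aqueous layer was extracted with ethyl acetate.",
    "WASH": "The combined organic layers were washed with brine.",
    "CONCENTRATION": "The solvent was removed under reduced pressure.",
    "DRY_WITH_MATERIAL": "The organic phase was dried over sodium sulfate.",
    "RECRYSTALLIZATION": "The crude solid was recrystallized from ethanol.",
    "DISTILLATION": "The residue was distilled under vacuum.",
    "CHROMATOGRAPHY": "The residue was purified by column chromatography.",
}
_TEXTURES = ("CRYSTAL", "POWDER", "OIL", "SOLID", "FOAM")
_COLORS = ("white", "pale yellow", "colorless", "off-white", "orange", "brown")
_TEMPERATURES = (0, 20, 25, 40, 60, 80, 100, 110)

# default per-name role frequencies: solvents are usually but not always
# solvents, catalysts usually catalysts; reactant-pool names are always
# reactants.  Ambiguous names exercise the popularity baseline.
DEFAULT_ROLE_FREQ = {"solvent": {"SOLVENT": 0.85, "REACTANT": 0.15},
                     "catalyst": {"CATALYST": 0.80, "REACTANT": 0.20},
                     "reactant": {"REACTANT": 1.0}}


@dataclass
class GenConfig:
    n_reactions: int = 100
    seed: int = 0  # mandatory; every record derives its stream from it
    inputs_range: tuple[int, int] = (1, 4)
    compounds_per_input: tuple[int, int] = (1, 2)
    workups_range: tuple[int, int] = (1, 5)
    yield_range: tuple[int, int] = (40, 99)
    p_omit_product_name: float = 0.0
    role_freq: dict = dc_field(default_factory=lambda: dict(DEFAULT_ROLE_FREQ))

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_omit_product_name <= 1.0:
            raise ValueError("p_omit_product_name must be in [0, 1]")


def _draw_role(rng: random.Random, freq: dict[str, float]) -> str:
    roles = sorted(freq)
    weights = [freq[r] for r in roles]
    return rng.choices(roles, weights=weights, k=1)[0]


def _reactant_name(rng: random.Random, used: set[str]) -> str:
    while True:
        name = f"{rng.choice(_PREFIXES)}{rng.choice(_CORES)}"
        if name not in used:
            used.add(name)
            return name


def _pick(rng: random.Random, pool: Sequence[str], used: set[str]) -> str:
    choices = [x for x in pool if x not in used]
    name = rng.choice(choices) if choices else f"{rng.choice(pool)} ({len(used)})"
    used.add(name)
    return name


def _fresh_number(rng: random.Random, used: set[float], draw) -> float:
    # amount values are unique within a record so any two generated
    # compounds differ in at least two leaves (name and amount), keeping
    # the optimal matching unambiguous under single-leaf alterations
    while True:
        v = draw(rng)
        if v not in used:
            used.add(v)
            return v


def _mass_amount(rng: random.Random, used: set[float]) -> dict:
    v = _fresh_number(rng, used, lambda r: round(r.uniform(0.1, 50.0), 2))
    return {"mass": {"value": v, "units": "GRAM"}}


def _volume_amount(rng: random.Random, used: set[float]) -> dict:
    v = _fresh_number(rng, used, lambda r: float(r.randrange(5, 500, 5)))
    return {"volume": {"value": v, "units": "MILLILITER"}}


def _amount_phrase(amount: dict) -> str:
    if "mass" in amount:
        return f"{amount['mass']['value']:g} g"
    if "volume" in amount:
        return f"{amount['volume']['value']:g} mL"
    return f"{amount['moles']['value']:g} mmol"


def gen_reaction(config: GenConfig, index: int) -> CorpusRecord:
    """Deterministically generate one (procedure text, record) pair."""
    rng = random.Random(f"{config.seed}:{index}")
    used: set[str] = set()
    used_values: set[float] = set()

    n_inputs = rng.randint(*config.inputs_range)
    inputs: dict[str, dict] = {}
    compounds: list[tuple[str, dict]] = []  # (name, component)
    solvent_names: list[str] = []
    for i in range(n_inputs):
        n_comp = rng.randint(*config.compounds_per_input)
        components = []
        for _ in range(n_comp):
            kind = "reactant"
            if i == n_inputs - 1 and not solvent_names:
                kind = "solvent"
            elif i > 0 and rng.random() < 0.25:
                kind = "catalyst"
            if kind == "solvent":
                name = _pick(rng, _SOLVENTS, used)
                amount = _volume_amount(rng, used_values)
                solvent_names.append(name)
            elif kind == "catalyst":
                name = _pick(rng, _CATALYSTS, used)
                amount = _mass_amount(rng, used_values)
            else:
                name = _reactant_name(rng, used)
                amount = _mass_amount(rng, used_values)
            comp = {
                "identifiers": [{"type": "NAME", "value": name}],
                "amount": amount,
                "reaction_role": _draw_role(rng, config.role_freq[kind]),
            }
            components.append(comp)
            compounds.append((name, comp))
        inputs[f"m{i + 1}"] = {"components": components}

    temp = rng.choice(_TEMPERATURES)
    conditions = {
        "temperature": {"setpoint": {"value": float(temp), "units": "CELSIUS"}},
        "stirring": {"type": "STIR_BAR"},
    }

    n_workups = rng.randint(*config.workups_range)
    workup_types = rng.sample(_WORKUP_TYPES, k=n_workups)
    workups = [
        {"type": t, "details": _WORKUP_SENTENCES[t]} for t in workup_types
    ]

    product_name = _reactant_name(rng, used)
    yield_pct = rng.randint(*config.yield_range)
    product_mass = round(rng.uniform(0.05, 20.0), 2)
    product = {
        "identifiers": [{"type": "NAME", "value": product_name}],
        "measurements": [
            {"type": "YIELD", "percentage": {"value": float(yield_pct)}},
            {"type": "AMOUNT", "amount": {"mass": {"value": product_mass, "units": "GRAM"}}},
        ],
        "texture": {"type": rng.choice(_TEXTURES)},
        "isolated_color": rng.choice(_COLORS),
        "reaction_role": "PRODUCT",
    }
    outcomes = [{"products": [product]}]

    omit_name = rng.random() < config.p_omit_product_name
    text = _render_text(
        compounds, solvent_names, temp, workup_types, product_name,
        product_mass, yield_pct, omit_name,
    )

    data = {
        "inputs": inputs,
        "conditions": conditions,
        "workups": workups,
        "outcomes": outcomes,
    }
    node = MessageNode(data=data, message_type="Reaction", spec=SchemaSpec.default())
    return CorpusRecord(record=node, procedure_text=text, source_id=f"rxn-{index:06d}")


def _render_text(
    compounds: list[tuple[str, dict]],
    solvent_names: list[str],
    temp: int,
    workup_types: list[str],
    product_name: str,
    product_mass: float,
    yield_pct: int,
    omit_product_name: bool,
) -> str:
    solvent_set = set(solvent_names)
    main = [(n, c) for n, c in compounds if n not in solvent_set]
    phrases = [f"{n} ({_amount_phrase(c['amount'])})" for n, c in main]
    if len(phrases) > 1:
        listing = ", ".join(phrases[:-1]) + " and " + phrases[-1]
    else:
        listing = phrases[0] if phrases else "the starting material"
    if solvent_names:
        solv = " and ".join(
            f"{n} ({_amount_phrase(c['amount'])})"
            for n, c in compounds if n in solvent_set
        )
        first = f"A solution of {listing} in {solv} was stirred at {temp} °C."
    else:
        first = f"A mixture of {listing} was stirred at {temp} °C."
    sentences = [first]
    sentences.extend(_WORKUP_SENTENCES[t] for t in workup_types)
    shown = "the title compound" if omit_product_name else product_name
    sentences.append(
        f"The product {shown} was obtained ({product_mass:g} g, {yield_pct}% yield)."
    )
    return " ".join(sentences)


def gen_corpus(config: GenConfig) -> list[CorpusRecord]:
    """``n_reactions`` records, byte-stable under the config seed."""
    return [gen_reaction(config, i) for i in range(config.n_reactions)]


# ---------------------------------------------------------------------------
# Perturbation engine
# ---------------------------------------------------------------------------

PERTURBABLE = ("Compound", "ProductCompound", "ReactionWorkup", "ReactionConditions")


@dataclass
class PerturbSpec:
    """Requested corruption counts per message type.

    ``counts[mtype] = (add, remove, alter)``.  ReactionConditions is a
    single message: only ``alter`` applies to it.
    """

    counts: dict[str, tuple[int, int, int]] = dc_field(default_factory=dict)

    def get(self, mtype: str) -> tuple[int, int, int]:
        return self.counts.get(mtype, (0, 0, 0))

    @property
    def is_noop(self) -> bool:
        return all(v == (0, 0, 0) for v in self.counts.values())


@dataclass
class PerturbEntry:
    message_type: str
    op: str  # add | remove | alter
    path: str
    before: object = None
    after: object = None


@dataclass
class PerturbationLog:
    entries: list[PerturbEntry] = dc_field(default_factory=list)

    def counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for e in self.entries:
            out.setdefault(e.message_type, {"add": 0, "remove": 0, "alter": 0})
            out[e.message_type][e.op] += 1
        return out

    def __len__(self) -> int:
        return len(self.entries)


class InfeasiblePerturbation(ValueError):
    pass


def _locate(data: dict, mtype: str) -> list[tuple]:
    """Addresses of all messages of a type: (container, key-or-index, path)."""
    sites: list[tuple] = []
    if mtype == "Compound":
        for key, inp in (data.get("inputs") or {}).items():
            comps = inp.get("components") or []
            for i in range(len(comps)):
                sites.append((comps, i, f'inputs["{key}"].components[{i}]'))
    elif mtype == "ProductCompound":
        for oi, outcome in enumerate(data.get("outcomes") or []):
            prods = outcome.get("products") or []
            for i in range(len(prods)):
                sites.append((prods, i, f"outcomes[{oi}].products[{i}]"))
    elif mtype == "ReactionWorkup":
        wk = data.get("workups") or []
        for i in range(len(wk)):
            sites.append((wk, i, f"workups[{i}]"))
    elif mtype == "ReactionConditions":
        if data.get("conditions") is not None:
            sites.append((data, "conditions", "conditions"))
    return sites


def _scalar_leaf_paths(msg: object, prefix: tuple = ()) -> list[tuple]:
    out: list[tuple] = []
    if isinstance(msg, dict):
        for k, v in msg.items():
            out.extend(_scalar_leaf_paths(v, prefix + (k,)))
    elif isinstance(msg, list):
        for i, v in enumerate(msg):
            out.extend(_scalar_leaf_paths(v, prefix + (i,)))
    else:
        out.append(prefix)
    return out


def _set_leaf(msg, keys: tuple, value) -> object:
    cur = msg
    for k in keys[:-1]:
        cur = cur[k]
    before = cur[keys[-1]]
    cur[keys[-1]] = value
    return before


def _fresh_value(before, counter: int):
    """A replacement value guaranteed distinct from anything generated."""
    if isinstance(before, bool):
        return not before
    if isinstance(before, (int, float)):
        return float(before) + 1000.0 + counter + 0.5
    return f"{before} [altered {counter}]"


def _fresh_message(mtype: str, rng: random.Random, counter: int) -> dict:
    if mtype == "Compound":
        return {
            "identifiers": [{"type": "NAME", "value": f"added compound {counter}"}],
            "amount": {"mass": {"value": 900.0 + counter, "units": "GRAM"}},
            "reaction_role": rng.choice(("REACTANT", "SOLVENT", "CATALYST")),
        }
    if mtype == "ProductCompound":
        return {
            "identifiers": [{"type": "NAME", "value": f"added product {counter}"}],
            "measurements": [
                {"type": "YIELD", "percentage": {"value": 900.0 + counter}},
            ],
            "reaction_role": "PRODUCT",
        }
    return {  # ReactionWorkup
        "type": rng.choice(_WORKUP_TYPES),
        "details": f"injected workup step {counter}",
    }


def perturb(
    record: MessageNode | CorpusRecord,
    spec: PerturbSpec,
    seed: int,
) -> tuple[MessageNode, PerturbationLog]:
    """Apply logged corruptions to a copy of ``record``.

    Alter and remove targets are sampled uniformly among eligible messages
    and are disjoint (an altered message is never also removed); altered
    leaf values are fresh and collide with nothing.  An infeasible request
    raises :class:`InfeasiblePerturbation` naming the short message type.
    """
    node = record.record if isinstance(record, CorpusRecord) else record
    data = copy.deepcopy(node.data) or {}
    rng = random.Random(seed)
    log = PerturbationLog()
    counter = 0

    for mtype in PERTURBABLE:
        n_add, n_remove, n_alter = spec.get(mtype)
        if mtype == "ReactionConditions" and (n_add or n_remove):
            raise InfeasiblePerturbation(
                "ReactionConditions is a single message; only alter applies"
            )
        sites = _locate(data, mtype)
        if n_remove + n_alter > len(sites):
            raise InfeasiblePerturbation(
                f"{mtype}: requested {n_remove} removals + {n_alter} alterations "
                f"but only {len(sites)} messages exist"
            )
        chosen = rng.sample(range(len(sites)), n_remove + n_alter)
        alter_idx = chosen[:n_alter]
        remove_idx = chosen[n_alter:]

        for si in alter_idx:
            container, key, path = sites[si]
            msg = container[key]
            leaves = _scalar_leaf_paths(msg)
            keys = rng.choice(leaves)
            counter += 1
            before = _set_leaf(msg, keys, None)
            after = _fresh_value(before, counter)
            _set_leaf(msg, keys, after)
            leaf_path = path + "".join(
                f"[{k}]" if isinstance(k, int) else f".{k}" for k in keys
            )
            log.entries.append(
                PerturbEntry(mtype, "alter", leaf_path, before=before, after=after)
            )

        # delete higher indices first so earlier addresses stay valid
        for si in sorted(remove_idx, key=lambda s: sites[s][1] if isinstance(sites[s][1], int) else 0, reverse=True):
            container, key, path = sites[si]
            before = container[key]
            if isinstance(key, int):
                del container[key]
            else:
                del container[key]
            log.entries.append(
                PerturbEntry(mtype, "remove", path, before=before, after=None)
            )

        for _ in range(n_add):
            counter += 1
            msg = _fresh_message(mtype, rng, counter)
            container_path = ""
            if mtype == "Compound":
                keys = sorted(data.get("inputs") or {})
                if not keys:
                    data.setdefault("inputs", {})["m1"] = {"components": []}
                    keys = ["m1"]
                key = rng.choice(keys)
                comps = data["inputs"][key].setdefault("components", [])
                pos = rng.randint(0, len(comps))
                comps.insert(pos, msg)
                container_path = f'inputs["{key}"].components[{pos}]'
            elif mtype == "ProductCompound":
                outcomes = data.setdefault("outcomes", [{}])
                prods = outcomes[0].setdefault("products", [])
                pos = rng.randint(0, len(prods))
                prods.insert(pos, msg)
                container_path = f"outcomes[0].products[{pos}]"
            else:
                wk = data.setdefault("workups", [])
                pos = rng.randint(0, len(wk))
                wk.insert(pos, msg)
                container_path = f"workups[{pos}]"
            log.entries.append(
                PerturbEntry(mtype, "add", container_path, before=None, after=msg)
            )

    out = MessageNode(data=data if data else None, message_type=node.message_type,
                      spec=node.spec)
    return out, log


def sample_perturb_spec(
    record: MessageNode | CorpusRecord,
    rng: random.Random,
    p_touch: float = 0.6,
) -> PerturbSpec:
    """A random feasible spec honoring the unambiguity guarantee: per
    message type, adds XOR removes (plus optional alters)."""
    node = record.record if isinstance(record, CorpusRecord) else record
    data = node.data or {}
    counts: dict[str, tuple[int, int, int]] = {}
    for mtype in ("Compound", "ProductCompound", "ReactionWorkup"):
        n = len(_locate(data, mtype))
        if n == 0 or rng.random() > p_touch:
            continue
        n_alter = rng.randint(0, min(2, n))
        n_add = n_remove = 0
        room = n - n_alter
        mode = rng.random()
        if mode < 0.4 and room > 0:
            n_remove = rng.randint(1, min(2, room))
        elif mode < 0.8:
            n_add = rng.randint(1, 2)
        if n_add or n_remove or n_alter:
            counts[mtype] = (n_add, n_remove, n_alter)
    if data.get("conditions") is not None and rng.random() < 0.3:
        counts["ReactionConditions"] = (0, 0, 1)
    return PerturbSpec(counts=counts)
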