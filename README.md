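# ordbench

A benchmark toolkit for **structured reaction-data extraction**: preparing
procedure-text → structured-record training corpora, repairing near-JSON
model output, and scoring extracted reaction records against ground truth.

Most synthetic organic chemistry is recorded as free-text procedure
paragraphs (patents, journals, ELNs). Converting those paragraphs into
structured records — in the style of the Open Reaction Database (ORD)
schema, where a `Reaction` message nests `inputs`, `conditions`, `workups`
and `outcomes` sub-messages with typed fields and strict enum vocabularies
— is a combined named-entity-recognition and relation-extraction task.
This package is for people building or evaluating such extractors: it
provides the corpus-preparation rules, the output-repair step, and above
all the evaluation metrics, together with a synthetic fixture generator
whose logged corruptions give every metric a known-answer oracle.

## The metrics

Both metrics are built on one edit distance for nested messages. For two
messages *a*, *b* of the same type,

```
d(a, b) = #{leaf paths present in exactly one of a, b}
        + #{shared leaf paths with unequal values}
```

with repeated sub-lists first aligned by the minimum-cost pairing of their
items (recursively), and `d(a, ∅) = ` number of populated leaves of *a*.

When a ground-truth list of messages `G` is compared with a predicted list
`P`, the shorter list is padded with empty messages and a bijection π
minimizing `Σ d(g, π(g))` is found (Hungarian method). The bijection
labels every pair with a failure mode:

| mode | meaning |
|---|---|
| **Accurate** | matched at distance 0 |
| **Alteration** | matched at distance > 0 |
| **Removal** | ground-truth message matched to a pad |
| **Addition** | predicted message matched to a pad |

**Metric 1 (message level)** counts these modes per message type (input
`Compound`, `ProductCompound`, `ReactionConditions`, `ReactionWorkup`).
**Metric 2 (leaf level)** counts the same modes per scalar leaf field,
bucketed by field type (identifiers, amount, reaction role, condition,
workup, other); every leaf of a removed message is a removal, every leaf
of an added message an addition. Metric 1 is the more stringent: a
message counted Accurate has zero leaf-level failures. A *lenient*
variant additionally treats two products as identical when their
identifiers and amounts agree (ignoring derived fields such as calculated
yield, texture, color), and ignores the inferred `reaction_role` for
input compounds.

The toolkit also scores **compound-name recognition** (minimum-cost
matching of name multisets under normalized edit distance) and **reaction
role classification** (REACTANT / SOLVENT / CATALYST confusion matrices
with MISSING/ERROR outcomes and macro-F1), including a **popularity
baseline** that predicts each compound's most frequent training-set role,
breaking ties and unseen names uniformly at random.

## Worked example

```python
from ordbench import GenConfig, PerturbSpec, evaluate_reaction, gen_reaction, perturb

rec = gen_reaction(GenConfig(seed=1), index=0)          # text + ground truth
pred, log = perturb(rec, PerturbSpec({                  # corrupt a copy:
    "Compound": (0, 1, 1),                              #   1 removal, 1 alteration
    "ReactionWorkup": (1, 0, 0),                        #   1 addition
}), seed=4)

res = evaluate_reaction(rec.record, pred)
for mtype, t in res.message_tallies.items():
    print(f"{mtype:18s} accurate={t.accurate} removal={t.removal} "
          f"addition={t.addition} alteration={t.alteration} total={t.total}")
```

prints

```
Compound           accurate=4 removal=1 addition=0 alteration=1 total=6
ProductCompound    accurate=1 removal=0 addition=0 alteration=0 total=1
ReactionWorkup     accurate=3 removal=0 addition=1 alteration=0 total=3
ReactionConditions accurate=1 removal=0 addition=0 alteration=0 total=1
```

The injected corruptions (one compound deleted, one compound's leaf
altered, one workup inserted) are recovered exactly; `total` is always the
ground-truth message count, so `accurate + removal + alteration = total`
while additions are counted on top. The `examples/` directory holds one
short script per capability (generation, corpus preparation, repair,
extraction scoring, name recognition, the role baseline).

A thin CLI wraps the same library calls:

```
ordbench generate -n 100 --seed 1 -o corpus.jsonl
ordbench evaluate --ground-truth corpus.jsonl --predictions preds.jsonl -o report.json
```

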