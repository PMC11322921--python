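# Methods

This note records the models, conventions, and numerical choices behind
ordbench, in the order a user meets them: the schema model, corpus
preparation, JSON repair, the evaluation metrics, name/role scoring, and
the synthetic-data generator that gives every metric a known-answer
oracle.

## Schema model

Records are nested messages in the style of the Open Reaction Database
(ORD): a `Reaction` holding `inputs` (a map label → `ReactionInput`),
`conditions` (a single message, never a list), `workups` (an ordered
list), and `outcomes` (products with measurements). The full ORD schema
has several hundred fields; ordbench ships a versioned vocabulary file
(`src/ordbench/data/schema_vocab.json`) covering the subset the toolkit
generates and scores — identifiers, amounts, reaction roles, temperature
and stirring conditions, workup types, and product yield/texture/color —
and validation is data-driven against that file, so the subset can be
extended without code changes.

Conventions:

* **Absent vs null.** Unpopulated fields are absent; explicit nulls and
  empty containers are stripped at parse time. This makes "populated leaf
  count", the basis of the distance, well defined.
* **Paths.** Dotted field names, zero-based bracketed list indices,
  double-quoted map keys: `inputs["m1"].components[0].identifiers[0].value`.
* **Enums.** Case-sensitive exact membership in the vocabulary, mirroring
  protobuf enum strictness; out-of-vocabulary strings are syntactic
  violations, reported per leaf, never raised.
* Malformed JSON raises a parse failure, a different signal from schema
  violations, because downstream the two are counted separately.

## Corpus preparation

A record is **admitted** when every reaction input lists at least one
component and a procedure paragraph is present. **Implicit-information
scrubbing** then removes structured content an extractor could not learn
from the text: NAME identifiers whose value never occurs in the paragraph,
and YIELD measurements whose integer value is not stated. Matching rules
(the loosest faithful reading of "explicitly stated"): names are searched
case-insensitively as substrings after whitespace normalization; yields by
their integer part as a decimal string under digit-boundary search, so a
recorded yield of 8 does not match "85%". Scrubbing is idempotent and
logged by path.

Prompt/completion examples are rendered from an instruction template
(Alpaca-style, shipped as a data file with `{instruction}`, `{input}`,
`{completion}` placeholders); the completion is the record's canonical
JSON (sorted keys). Deduplication keys on the prompt string only, keeping
the first occurrence; a repeated prompt with a different completion is
logged as a conflict. The token-length filter defaults to an inclusive
limit of 2048 — "limit of N" is read as ≤ N — under a deterministic
whitespace-plus-punctuation tokenizer; counts are tokenizer-dependent and
any `str -> int` callable (e.g. a subword tokenizer) can be plugged in.
The 8:1:1 train/validation/test split uses a seeded shuffle followed by
largest-remainder apportionment, so 10 examples split 8/1/1 exactly and
two runs with one seed agree assignment-for-assignment.

## JSON repair

Valid input is a byte-identical fixed point. Otherwise a single
left-to-right lenient pass re-reads the text, tolerating unterminated
strings (closed at end of line or text), unquoted keys and values
(quoted, with `true`/`false`/`null`/numbers kept literal), missing commas
and colons, trailing commas, mismatched or missing closing brackets
(a stray `}` inside an array closes the array and is left for the
enclosing object), and trailing garbage; a deleted root `{` is recovered
by retrying with the brace restored. Content is never reordered; every
fix is logged as `(position, action)`. The repaired text is a
re-serialization of the recovered value, hence always valid JSON;
"failure" (no value recoverable, e.g. empty input) is a result state, not
an exception. The property the fuzz suite enforces is that every
single-character deletion of a bracket or quote from a valid record is
repaired to parseable JSON — parseable, not semantically identical: a
deletion can legitimately merge content into a string, and judging the
damage is the evaluator's job, not the repairer's.

## Evaluation metrics

The distance between two same-type messages is the number of leaf paths
present in exactly one plus the number of shared paths with unequal
values; repeated sub-lists inside a message are first aligned by the
minimum-cost pairing of their items, recursively, so index shifts and
reorderings do not create spurious alterations. The distance to the empty
message is the populated leaf count. Scalar equality parses numbers
(5 == 5.0) and trims outer whitespace on strings, so serialization
dialects cost nothing.

List matching pads the shorter list with empty messages and solves the
assignment with the Hungarian method (`scipy.optimize.linear_sum_assignment`),
then refines ties lexicographically by (ground-truth index, prediction
index) via optimal-completion checks, so reports are byte-stable. Pads
exist only on the shorter side, so a pad can never pair with a pad.
Failure modes follow from the matched pairs, and leaf-level attribution
walks the same recursive alignment the distance used, guaranteeing
consistency: the distance equals the number of non-accurate leaf outcomes
of the pair.

One consequence of the padding rule is worth stating plainly: if one
record simultaneously loses one message and gains another of the same
type, the two lists have equal lengths, no pads exist, and the optimal
bijection must pair the removed original with the added stranger —
reported as an alteration, not a removal plus an addition. This is
inherent to padded bijective matching, and the synthetic generator's
oracle specs avoid the cancellation (see below).

The **lenient** equivalence treats two products as identical when their
identifier multisets and all amount-bearing leaves agree, ignoring
derived fields (calculated yield, texture, isolated color); for input
compounds it ignores `reaction_role` only. Lenient tallies upgrade
qualifying alterations to accurate; removals/additions are untouched.

`ReactionConditions` is one message, so only Accurate and Alteration
apply; a prediction missing its conditions is an alteration whose leaves
are all removals. A wholly unparseable prediction counts as the removal
of every ground-truth message. Reported percentages use one decimal,
rounded half-up, with additions reported over the same ground-truth
denominator as the other modes; zero denominators render as an undefined
marker. The summary "mean message accuracy" is the unweighted mean of
per-type accuracies, using the lenient figure where one is defined.

Field-type buckets for Metric 2: all condition leaves → *condition*, all
workup leaves → *workup*; within compounds and products, leaves under
`identifiers` → *identifiers*, under `amount` (including the amount
inside product measurements) → *amount*, `reaction_role` →
*reaction_role*; everything else (measurement types, yield percentages,
texture, color) → *other*.

## Name and role scoring

Names are normalized by trimming and collapsing internal whitespace;
case is preserved because chemical names are case-meaningful. Name
multisets are matched by minimum total cost where `cost(a, b)` is the
normalized Levenshtein distance (edlib) in [0, 1] and pairing with a pad
costs 1 + ε — the ε prefers pairing two maximally different real names
(one alteration) over a removal plus an addition, a documented
convention since the four-column taxonomy does not itself define name
alteration.

Role classification restricts to REACTANT / SOLVENT / CATALYST for input
compounds (products always carry PRODUCT). The confusion matrix pairs
compounds with the same optimal matching as Metric 1; an unmatched
ground-truth compound is MISSING, a matched one under a different name is
ERROR, and a matched, correctly named compound with a missing or invalid
predicted role is counted ERROR too (the compound is present; its
extraction is wrong). Rows are normalized by true-instance counts.
Macro-F1 averages per-role F1 over the three classes; MISSING/ERROR are
false negatives of the true role and false positives of no role, and a
class with neither true nor predicted instances contributes 0 (the
average is undefined only for an all-empty matrix). The popularity
baseline takes the argmax of training-set role counts per name; ties and
unseen names draw uniformly. Given an integer seed the draw is a pure
function of (name, seed) via a CRC32 mix, so predictions are reproducible
and order-independent; passing a shared `random.Random` instead gives
i.i.d. draws for Monte-Carlo work.

## Synthetic data

The generator emulates the register of patent procedure paragraphs: 1–4
inputs each holding 1–2 named, quantified compounds (masses in grams,
solvent volumes in millilitres), a temperature setpoint and stirring
condition, 1–5 distinct typed workups with template sentences, and one
product with an integer yield (40–99%), a mass, texture, and color.
Compound names combine substituent prefixes with ring/functional cores,
plus real solvent and catalyst names; roles are drawn per name from a
configurable frequency table (by default solvents are SOLVENT with
probability 0.85, catalysts CATALYST with 0.80, else REACTANT), which is
what makes the popularity baseline's expected behavior analytically
computable. In the default "consistent" mode every name and the integer
yield appear verbatim in the text, so scrubbing provably removes nothing;
`p_omit_product_name` replaces the product name with "the title
compound" in the text to exercise the scrubbing rule. All randomness is
a pure function of (seed, record index).

What the generator does **not** emulate: linguistic variety (passive
constructions, abbreviations, nested clauses), chemically meaningful
structures or stoichiometry, multi-product outcomes, and cross-record
name ambiguity beyond the role table. Passing metric-recovery tests
therefore shows the metrics are computed correctly, not that any
particular extractor is good at real prose.

The perturbation engine applies requested per-type (add, remove, alter)
counts to a copy of a record and logs every operation with its path and
before/after values. Alterations rewrite one scalar leaf to a fresh
value (numeric offset ≥ 1000, or a marked string) and amount values are
unique within a record, so every corrupted message stays strictly closer
to its origin than to any other message and the optimal matching is
unambiguous. Because of the add/remove cancellation described above, the
sampled oracle specs apply adds XOR removes per message type per record;
that restriction — fresh values, spaced amounts, add-xor-remove — is the
"unambiguity guarantee" under which recovery of the log is exact at both
metric levels.

## Problem sizes and tolerances

The shipped verification uses sizes chosen to make the checks exhaustive
rather than large: the matcher is audited against a brute-force oracle on
1000 random instances with list lengths ≤ 6 (where all bijections can be
enumerated); perturbation recovery runs on 500 generated reactions;
uniformity of tie-breaking uses 10 000 draws against 3σ binomial bands;
the baseline's confusion matrix is compared to its analytic expectation
at 2000 occurrences per name, 3σ per cell; the repair fuzz suite
enumerates every single bracket/quote deletion over a 10-record corpus
(a few thousand cases). Percent arithmetic is exact decimal
(half-up), not floating point.

## Known limitations

* The nested edit distance is a fixed, documented definition (unit cost
  per missing/extra/unequal leaf); parity with any external nested-diff
  utility is not claimed, and nesting levels are weighted uniformly.
* The schema vocabulary is a best-effort subset; records using other ORD
  fields validate as "unknown field" until the vocabulary file is
  extended.
* The repair heuristics are a documented subset sufficient for the fuzz
  family they are tested on; adversarial near-JSON can defeat them.
* Numeric tolerance scoring is deliberately absent: quantities compare by
  exact match (after numeric parse), since a misplaced number is treated
  as no better than a wrong one.
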