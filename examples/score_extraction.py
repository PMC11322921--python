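"""Score corrupted 'predictions' against ground truth with the two
edit-distance metrics and print the summary tables.

Run:  python examples/score_extraction.py
"""

import random

from ordbench import (
    GenConfig,
    aggregate_report,
    aggregate_results,
    evaluate_reaction,
    gen_corpus,
    perturb,
)
from ordbench.reports import render_leaf_table, render_message_table
from ordbench.synthetic import sample_perturb_spec

corpus = gen_corpus(GenConfig(n_reactions=100, seed=5))
rng = random.Random(5)

results = []
for i, rec in enumerate(corpus):
    spec = sample_perturb_spec(rec, rng)  # random add/remove/alter corruptions
    pred, log = perturb(rec, spec, seed=i)
    results.append(evaluate_reaction(rec.record, pred))

report = aggregate_report(aggregate_results(results))
print("Message level (how many whole messages were extracted accurately,")
print("or erroneously removed, added, or altered):\n")
print(render_message_table(report))
print("Leaf level (the same failure modes per scalar field, by field type):\n")
print(render_leaf_table(report))
print(f"Unweighted mean of per-type message accuracies: "
      f"{report['message_accuracy_mean_pct']}%")
print(f"Unweighted mean of per-field-type leaf accuracies: "
      f"{report['leaf_accuracy_mean_pct']}%")
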