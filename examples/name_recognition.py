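"""Score compound-name recognition: the multiset of names in a predicted
record against the ground-truth names.

Run:  python examples/name_recognition.py
"""

from ordbench import compare_names

# an unrecognized referencing token: "9" has no counterpart -> removal
gt = ["tryptophan methyl ester", "9"]
pred = ["tryptophan methyl ester"]
t = compare_names(gt, pred)
print(f"gt={gt}  pred={pred}")
print(f"  accurate={t.accurate} removal={t.removal} addition={t.addition} "
      f"alteration={t.alteration}\n")

# an over-extracted NMR artifact: "1H" is an extra entity -> addition
gt = ["4-chloroaniline"]
pred = ["4-chloroaniline", "1H"]
t = compare_names(gt, pred)
print(f"gt={gt}  pred={pred}")
print(f"  accurate={t.accurate} removal={t.removal} addition={t.addition} "
      f"alteration={t.alteration}\n")

# a near-miss spelling pairs up instead of splitting into removal+addition
gt = ["4-chloroaniline"]
pred = ["4-chloroanilin"]
t = compare_names(gt, pred)
print(f"gt={gt}  pred={pred}")
print(f"  accurate={t.accurate} removal={t.removal} addition={t.addition} "
      f"alteration={t.alteration}\n")

print(
    "Names pair up by minimum total normalized edit distance with unmatched\n"
    "names costing 1, so close spellings count as a single alteration while\n"
    "genuinely missing or extra entities count as removals or additions."
)
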