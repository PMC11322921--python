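"""Generate a synthetic procedure/record pair and inspect its structure.

Run:  python examples/generate_and_inspect.py
"""

from ordbench import GenConfig, SchemaSpec, gen_reaction, leaf_fields, validate_record

rec = gen_reaction(GenConfig(seed=1), index=0)

print("Procedure text:")
print(" ", rec.procedure_text, "\n")

print("Leaf fields of the structured record (path = value):")
for path, value in leaf_fields(rec.record):
    print(f"  {path} = {value!r}")

report = validate_record(rec.record, SchemaSpec.default())
print(f"\nSchema violations: {len(report.violations)}")
print(
    "Every populated scalar above is one 'leaf'; the record groups them into\n"
    "messages (compounds, conditions, workups, products) which are the units\n"
    "of message-level scoring."
)
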