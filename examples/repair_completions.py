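"""Repair near-JSON model completions before validation.

Run:  python examples/repair_completions.py
"""

from ordbench import repair_json

CASES = [
    '{"type": NAME}',                      # bare enum string
    '{"a": 1, "b": [1, 2,], }',            # trailing commas
    '{"workups": [{"type": "FILTRATION"}', # unclosed brackets
    '{"value": "unterminated',             # unterminated string
]

for text in CASES:
    res = repair_json(text)
    print(f"input   : {text}")
    print(f"repaired: {res.repaired_text}")
    print(f"actions : {[a for _, a in res.actions]}\n")

print(
    "Each action is a local string-level fix (insert-quote, insert-bracket,\n"
    "delete-trailing-comma, truncate-garbage); content is never reordered,\n"
    "and already-valid JSON is returned byte-identical."
)
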