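"""Inspect the generated rule bases of both fuzzy models.

Enumerates the antecedent spaces (972 combinations for the risk model,
108 for the injury model), shows how the severity policies distribute
consequents, and prints a few generated rules alongside the published
example rows they are pinned to.
"""

from collections import Counter

import cervidx as cx
from cervidx.risk import load_printed_risk_rules

for name, model in (("risk", cx.build_risk_model()),
                    ("injury", cx.build_injury_model())):
    space = cx.enumerate_rule_space(model)
    consequents = Counter(r.consequent for r in model.rules)
    disabled = sum(not r.enabled for r in model.rules)
    print(f"{name} model: {len(space)} antecedent combinations")
    print(f"  consequents: {dict(consequents)}, disabled: {disabled}")

print("\nfirst four published risk rows vs the generated base:")
model = cx.build_risk_model()
by_ante = {tuple(sorted(r.antecedent.items())): r.consequent for r in model.rules}
for row in load_printed_risk_rules()[:4]:
    ante = {v: model.input_by_name(v).canonical(l) for v, l in row.antecedent.items()}
    got = by_ante[tuple(sorted(ante.items()))]
    print(f"  {list(ante.values())} -> {got} (published: {row.consequent})")

print("\nDisabled rules are physically impossible combinations (sexual onset "
      "in an older age bracket than the current age; nucleoli detected "
      "inside hyperchromatic nuclei) and never fire.")
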