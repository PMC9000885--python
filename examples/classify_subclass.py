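"""Flavonoid subclass classification from diagnostic fragmentation rules.

Run:  python examples/classify_subclass.py
"""

from flavotier import (
    CompoundTemplate,
    SimulationConfig,
    classify,
    compound_formula,
    simulate_spectrum,
)

# A noisy spectrum of liquiritigenin (a flavanone).  Classification
# enumerates every substituent placement of every subclass skeleton that
# matches the precursor formula and verifies each rule.
t = CompoundTemplate("liquiritigenin", "flavanone",
                     {"hydroxyl": 1}, {"hydroxyl": 1})
spectrum = simulate_spectrum(t, SimulationConfig(seed=8))
result = classify(spectrum, compound_formula(t))

print("subclasses passing their fragmentation rule:")
for subclass, verdict in result.ranking:
    print(f"  {subclass:12s} explained intensity {verdict.explained_fraction:.0%}")
print("\nwhy the others fail:")
for subclass, reason in sorted(result.failures.items()):
    print(f"  {subclass:18s} {reason[:70]}")

# Flavanones and chalcones share their cleavage arithmetic, so both pass
# with identical scores: MS/MS alone cannot tell them apart.
print("\ntied top set:", ", ".join(sorted(result.top_set)))
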