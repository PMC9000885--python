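"""Retro-Diels-Alder fragments and neutral-loss cascades.

Run:  python examples/rda_fragments.py
"""

from flavotier import (
    CompoundTemplate,
    F,
    FragmentIon,
    IonSpec,
    ion_mz,
    loss_series,
    rda_fragment_ions,
    theoretical_spectrum,
)

# Daidzein: isoflavone skeleton with one hydroxyl on each aromatic ring.
# The 1,3 C-ring cleavage splits it into an A-ring acylium-type fragment
# and a B-ring styrene-type fragment; both keep their ring's substituents,
# so the pair m/z reads out the substitution pattern.
daidzein = CompoundTemplate("daidzein", "isoflavone",
                            {"hydroxyl": 1}, {"hydroxyl": 1})
for ion in rda_fragment_ions(daidzein, "1,3"):
    print(f"{ion.label:12s} {str(ion.formula):8s} m/z {ion.mz:.4f}")

# Carbonyl-bearing subclasses shed CO stepwise; starting from a lactone
# precursor cation this prints the familiar -28.0095 ladder.
start = FragmentIon("[M+H]+", F("C15H9O5"),
                    ion_mz(IonSpec(F("C15H9O5"), "cation")), "even")
for ion in loss_series(start, [F("CO")], depth=2):
    print(f"{ion.label:14s} m/z {ion.mz:.4f}")

# The full theoretical diagnostic spectrum (base peak normalized to 100):
sp = theoretical_spectrum(daidzein)
print(f"\n{daidzein.name} diagnostic spectrum (precursor {sp.precursor_mz:.4f}):")
for p in sp.peaks:
    print(f"  m/z {p.mz:9.4f}  {p.intensity:5.1f}")
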