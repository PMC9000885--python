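"""Fragmentation-tree annotation of an MS/MS peak list.

Run:  python examples/fragmentation_tree.py
"""

from flavotier import F, Peak, Spectrum, build_tree, tree_losses

# Four observed peaks of a dihydroxyflavanone ([M+H]+ = C15H13O4+).
# Every fragment must be a subformula of the precursor cation; edges are
# the neutral losses connecting them.
spectrum = Spectrum(
    identifier="dihydroxyflavanone",
    precursor_mz=257.0803,
    peaks=(
        Peak(257.0803, 40.0),
        Peak(153.0188, 100.0),
        Peak(131.0496, 30.0),
        Peak(103.0544, 60.0),
    ),
)
tree = build_tree(spectrum, F("C15H13O4"), tol_mda=10.0)
print(tree.to_outline())

# The loss multiset is the compact readout: styrene (C8H8) marks the
# retro-Diels-Alder ring opening, CO the carbonyl extrusion.
print("\nneutral losses:", ", ".join(sorted(str(l) for l in tree_losses(tree))))
print(tree.to_edge_table().to_string(index=False))
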