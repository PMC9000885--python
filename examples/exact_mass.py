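"""Exact-mass reasoning: formula masses, ion m/z and CHO decomposition.

Run:  python examples/exact_mass.py
"""

from flavotier import F, IonSpec, decompose, ion_mz, mass_error, monoisotopic_mass

# The isoflavone formononetin, C16H12O4.  Its protonated ion is what the
# instrument sees in positive mode; the proton adds 1.007276 Da because
# the electron leaves with the charge.
neutral = F("C16H12O4")
mz = ion_mz(IonSpec(neutral, "[M+H]+"))
print(f"formononetin M        = {monoisotopic_mass(neutral):.4f} Da")
print(f"formononetin [M+H]+   = {mz:.4f}")

# An instrument reported 269.0806 for this ion; the error is well inside
# the 5 mDa gate used for reference-standard matching.
err = mass_error(269.0806, mz)
print(f"observed 269.0806     -> {err.mda:+.1f} mDa ({err.ppm:+.1f} ppm)")

# Going the other way: which CHO formulas could an observed ion be?
# The first candidate (smallest |error|) is the right one.
candidates = decompose(269.0806, "[M+H]+", tol_mda=5.0)
print("decomposition of 269.0806:", ", ".join(str(f) for f in candidates))
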