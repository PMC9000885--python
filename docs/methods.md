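# Methods

This note records the models, conventions and numerical choices behind
`flavotier`, in the order the data flows.

## Mass arithmetic

All m/z values derive from a four-element monoisotopic table (C 12 exactly,
H 1.00782503207, O 15.9949146196, Na 22.9897692809 Da) stored as data in
`flavotier/data/elements.yaml`, plus the electron mass 5.4858e-4 Da. Every
+1 ion is electron-corrected: a proton adds 1.007276 Da, not the hydrogen
atom mass. This is not pedantry — the CO-loss anchor ions of the coumestan
family (241.0495, 213.0546) only agree to four decimals with the electron
subtracted.

Formulas are element-count multisets with exact integer arithmetic; the
all-zero formula is representable and is the identity of addition, so the
root of a fragmentation tree and a self-difference need no special cases.
Subtraction that would go negative raises.

Formula decomposition of an observed mass is an exhaustive scan over CHO
bounds (defaults C ≤ 30, H ≤ 40, O ≤ 15 in the pipeline), filtered by
RDBE ∈ [0, 25] and H ≤ 2C + 2 — the loosest filters that are still
chemically sane for CHO natural products — and sorted by absolute error
with fewer oxygens breaking ties. Na participates only as an adduct, never
in the decomposition alphabet, matching the acquisition convention of the
positive-mode flavonoid workflow (adducts [M+H]+, [M+Na]+, [2M+H]+; all
ions singly charged).

## Spectra, matching, similarity

A spectrum is an m/z-sorted peak list under a precursor; peaks more than
0.5 Th above the precursor are rejected at construction (isotope-spillover
guard). Peak matching between two spectra is greedy on descending
intensity product within an absolute window (default 10 mDa, inclusive),
each peak used at most once. Absolute mDa rather than ppm follows the
tolerance convention of the high-resolution workflow this package models;
the greedy rule is a declared stand-in for the undocumented internals of
commercial search engines — it is deterministic and order-independent
after the stated sort.

The dot-product score is the standard normalized cosine over the full
peak vectors (unmatched peaks keep their weight in the norms), with raw
intensities — no m/z^k weighting, because no published weighting exists
for the engines being emulated and raw is the simplest defensible choice.
The entropy score normalizes each spectrum to unit total intensity and
computes 1 − (2·S_merged − S_a − S_b)/ln 4 with Shannon entropies in
natural log and the merged spectrum the peak-aligned average; the cited
low-entropy re-weighting variant is deliberately omitted (no detail to
follow). Scores are reported as percentages; the library-search cutoff
(80) is inclusive, the quasi-reference promotion cutoff (90) strict,
mirroring the wording "cutoff, 80" versus "higher than 90 %".

## Flavonoid chemistry registry

The twelve subclass skeletons live in `flavotier/data/skeletons.yaml` as
human-editable data, not code: scaffold formula, a SMILES with mapped
substitution sites, the i,j bond-pair cleavage templates, the
diagnostic-ion emission table and the verification rule. Cleavage
templates are explicit part formulas rather than the output of a general
graph algorithm, because the neoflavonoid bond labels (5,10a and friends)
have no algorithmic definition — they are transcriptions. Two invariants
guard the transcription: part_A + part_B must equal the scaffold exactly
(asserted at load), and every emitted ion must embed in the protonated
molecule (water-transfer ions may exceed it by exactly one H2O).

Ring-A substituents travel with the A-part of a cleavage, ring-B
substituents with the B-part. Supported substituents are hydroxyl (+O),
methoxyl (+CH2O) and methyl (+CH2), which covers the fixture chemotypes;
glycosides and methylenedioxy bridges are out of scope. Ion forms are
protonated even-electron ([part+H]+), bare cation, or radical cation —
the aurone 1,3B and neoflavonoid-IV 1,2B base peaks are radicals, which
is why their printed m/z values are even-mass.

Theoretical diagnostic spectra use a three-tier intensity convention:
base peak 100, "strong/abundant" ions 60, others 20. The tiers are an
artifact convention (the source literature is qualitative); the one
quantitative statement — the flavanone/chalcone [1,3A+H]+ base peak
carries more than 40 % of total fragment intensity — is enforced by
boosting that ion to 1.2× the sum of the other fragments before
normalization, landing it near 55 % so that decoy peaks and intensity
noise cannot drag it under the 40 % verification threshold.

Where the neoflavonoid part formulas could not be transcribed from
drawings (types I–IV and VIII), they were chosen to conserve mass exactly
and to reproduce the printed anchor ions of each subclass
(123.044-type A fragments, the 241.0495/213.0546 CO ladder, 157.0648,
the even-mass 138.031-type radical, and the 215.03/243.07/115.05/226.06
family). They are representative, not structure-proven, and the
registry flags make them reviewable in one place.

## Rules and classification

A subclass rule has mandatory diagnostics (all must match a peak at the
MS2 tolerance), supporting diagnostics (ranking only), a base-peak
condition (the spectrum's base peak must be the named ion) and optionally
the 40 % share condition. The verdict is pass/fail; the
explained-intensity fraction (matched peak intensity over total) ranks
passing subclasses but never flips a verdict. Classification enumerates,
for each skeleton, every placement of the formula difference into ring
substituents (at most 3 O-bearing substituents and 2 methyls per ring —
the fixture chemotype bound, keeping enumeration O(small)) and keeps the
best verdict per subclass. Flavanones and chalcones share identical
cleavage arithmetic by construction and therefore always tie; callers
treat them as one equivalence class, which is the honest representation
of a genuine MS/MS indistinguishability (UV discrimination is out of
scope).

## Fragmentation trees

Peak annotation assigns each peak the carbon-containing subformula of the
precursor cation with least absolute error inside the tolerance; peaks
with no such subformula stay unannotated. Tree construction is a
deterministic best-parent heuristic rather than an exact maximum-scoring
tree: nodes attach in descending m/z to the already-placed heavier node
minimizing (loss not composable from ≤ 2 common losses, loss mass), with
ties broken by mass error then input order. The common-loss list is CO,
H2O, CH2O, C2H2O, CH3•, CH4, CO2 and styrene C8H8 (the RDA complement of
dihydro-C-ring flavonoids). Radical losses are limited to one per
root-to-leaf path (even-electron rule, configurable), and losses
consisting of more than two bare hydrogens are forbidden — they would
only ever be jitter artifacts. The tree is used as a readable neutral-loss
summary; no published tree score exists to optimize against, so it is
validated structurally (connectivity, edge conservation, |edges| =
|nodes| − 1).

## In-silico fragmentation

For structure ranking, a template is rendered as an RDKit molecule
(skeleton SMILES decorated at mapped ring sites) and fragmented by
deleting up to two acyclic heavy-atom bonds or one within-ring bond pair;
each connected component is emitted with ±1 H-transfer variants. This is
the iterative bond-breaking model of structure-database engines, kept to
two breaks because the diagnostic ions of interest (RDA cores,
substituent losses) are all reachable there and the candidate pool stays
small.

## The tiering pipeline

Level 1 requires all three orthogonal gates: |ΔRT| ≤ 0.05 min, precursor
error ≤ 5 mDa, and ≥ 3 matched fragment ions at 10 mDa (the source
criterion says only "matching fragment ions"; 3 is the configurable
default). Level 2a is the library search at cutoff 80 with a 10 mDa MS1
pre-filter. Level 2b ranks precursor-compatible structure candidates by
explained intensity over diagnostic ∪ in-silico ions and is accepted only
when the top candidate's subclass rule verifies; tied positional isomers
are reported jointly and flagged indistinguishable. Level 3 requires a
formula decomposition, a fragmentation tree and a non-empty subclass
ranking (a candidate set, not a unique structure); a unique formula alone
is level 4, otherwise level 5. Rule validation is recorded for levels
2a–3 but demotes nothing at 2a — it is a verification annotation, as in
the workflow being modeled. Adding evidence can only move a query toward
level 1, never away. Report ordering and number formatting are fixed, so
identical inputs give byte-identical TSVs.

## Synthetic data: what it emulates and what it does not

The 39-compound fixture carries the 18 purchased standards by name with
their real substitution patterns (one exception, recorded in the compound
table: "tangeretin" is kept in the flavanone group to preserve the
subclass census of 4 flavones, as a representative flavanone-skeleton
template with five methoxyls) and fills the remaining 21 entries with
representative quasi-reference templates of the stated subclasses.
Retention times are a synthetic 0.75-min grid starting at 3 min — no RT
model exists in the source material, and the spacing makes the 0.05-min
window discriminating in tests.

The noise model: Gaussian m/z jitter with σ = 3 mDa on fragments and
σ = 1 mDa on the precursor (MS1 on an Orbitrap is substantially more
accurate than HCD MS2 centroids, and the level-1 gate is 5 mDa on MS1),
5 % multiplicative intensity noise, five uniform decoy peaks at 5 %
relative intensity below the precursor, and 0.01-min RT jitter. All
randomness flows from one integer seed. The benchmark generator
partitions compounds into precursor-mass collision groups (20 mDa
union) before assigning designed levels, so a withheld compound can
never be "found" through an isomer's library record — without this the
design would be unscoreable, since the fixture deliberately contains
isomer families.

What the simulator does not emulate: collision-energy dependence of
intensities, isotope envelopes, chromatographic peak shapes, co-elution
and matrix effects, in-source fragmentation. Passing the synthetic
benchmark therefore demonstrates the internal consistency and
discriminative power of the rule/tier machinery under calibrated noise —
not performance on real instrument files, where intensity conventions
differ by instrument and the decoy structure is adversarial rather than
uniform.

## Problem sizes and determinism

The shipped benchmarks are desk-scale: 200 simulated spectra for the
rule-recovery and level-recovery experiments (seconds on one CPU), 50
random targets against the brute-force decomposition oracle, 200 random
pairs for similarity properties. Property tests are seeded (hypothesis
derandomized by fixed seeds via numpy generators), and every simulation
consumes its seed through `numpy.random.default_rng` with per-query
spawned integers, so reruns are bit-reproducible.

## Known limitations

Positional isomers within a subclass are not distinguishable (real
spectra cannot do it either at this evidence level, and the package says
so rather than guessing). Negative ion mode, multiply charged ions,
elements beyond C/H/O/Na, glycosylated and acylated flavonoids,
biflavones, and the machine-learning stages of de-novo tools (fingerprint
prediction, compound-class neural networks) are out of scope. The
commercial engines' undocumented score weightings are not reproduced;
their printed scores are not targets.
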