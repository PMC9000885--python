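# The 39 (quasi) reference compounds: 4 flavones, 6 flavonols,
# 9 isoflavones, 1 aurone, 6 flavanones, 2 chalcones, 2 flavanols,
# 4 neoflavonoids I, 1 neoflavonoid II, 1 neoflavonoid III,
# 2 neoflavonoids IV and 1 neoflavonoid VIII.
#
# The 18 purchased reference standards are carried by name with their real
# substitution patterns (tangeretin is the one representative exception:
# it is kept in the flavanone group to preserve the subclass composition,
# with five methoxyls on the flavanone skeleton).  Quasi-reference entries
# are representative templates of the stated subclass: real structures
# where well known, generic names otherwise.
#
# ring_a / ring_b substituents: hydroxyl (+O), methoxyl (+CH2O), methyl (+CH2).

compounds:
  # -- reference standards ---------------------------------------------------
  - {name: baicalein, skeleton: flavone, ring_a: {hydroxyl: 3}, provenance: reference}
  - {name: apigenin, skeleton: flavone, ring_a: {hydroxyl: 2}, ring_b: {hydroxyl: 1}, provenance: reference}
  - {name: wogonin, skeleton: flavone, ring_a: {hydroxyl: 2, methoxyl: 1}, provenance: reference}
  - {name: acacetin, skeleton: flavone, ring_a: {hydroxyl: 2}, ring_b: {methoxyl: 1}, provenance: reference}
  - {name: galangin, skeleton: flavonol, ring_a: {hydroxyl: 2}, provenance: reference}
  - {name: quercetin, skeleton: flavonol, ring_a: {hydroxyl: 2}, ring_b: {hydroxyl: 2}, provenance: reference}
  - {name: isorhamnetin, skeleton: flavonol, ring_a: {hydroxyl: 2}, ring_b: {hydroxyl: 1, methoxyl: 1}, provenance: reference}
  - {name: glycitein, skeleton: isoflavone, ring_a: {hydroxyl: 1, methoxyl: 1}, ring_b: {hydroxyl: 1}, provenance: reference}
  - {name: genistein, skeleton: isoflavone, ring_a: {hydroxyl: 2}, ring_b: {hydroxyl: 1}, provenance: reference}
  - {name: calycosin, skeleton: isoflavone, ring_a: {hydroxyl: 1}, ring_b: {hydroxyl: 1, methoxyl: 1}, provenance: reference}
  - {name: daidzein, skeleton: isoflavone, ring_a: {hydroxyl: 1}, ring_b: {hydroxyl: 1}, provenance: reference}
  - {name: formononetin, skeleton: isoflavone, ring_a: {hydroxyl: 1}, ring_b: {methoxyl: 1}, provenance: reference}
  - {name: isoliquiritigenin, skeleton: chalcone, ring_a: {hydroxyl: 1}, ring_b: {hydroxyl: 1}, provenance: reference}
  - {name: naringenin, skeleton: flavanone, ring_a: {hydroxyl: 2}, ring_b: {hydroxyl: 1}, provenance: reference}
  - {name: tangeretin, skeleton: flavanone, ring_a: {methoxyl: 3}, ring_b: {methoxyl: 2}, provenance: reference}
  - {name: liquiritigenin, skeleton: flavanone, ring_a: {hydroxyl: 1}, ring_b: {hydroxyl: 1}, provenance: reference}
  - {name: taxifolin, skeleton: flavanol, ring_a: {hydroxyl: 2}, ring_b: {hydroxyl: 2}, provenance: reference}
  - {name: dihydromyricetin, skeleton: flavanol, ring_a: {hydroxyl: 2}, ring_b: {hydroxyl: 3}, provenance: reference}

  # -- quasi reference standards promoted from high-scoring library hits -----
  - {name: kaempferol, skeleton: flavonol, ring_a: {hydroxyl: 2}, ring_b: {hydroxyl: 1}, provenance: quasi-reference-2a}
  - {name: myricetin, skeleton: flavonol, ring_a: {hydroxyl: 2}, ring_b: {hydroxyl: 3}, provenance: quasi-reference-2a}
  - {name: rhamnetin, skeleton: flavonol, ring_a: {hydroxyl: 1, methoxyl: 1}, ring_b: {hydroxyl: 2}, provenance: quasi-reference-2a}
  - {name: biochanin A, skeleton: isoflavone, ring_a: {hydroxyl: 2}, ring_b: {methoxyl: 1}, provenance: quasi-reference-2a}
  - {name: prunetin, skeleton: isoflavone, ring_a: {hydroxyl: 1, methoxyl: 1}, ring_b: {hydroxyl: 1}, provenance: quasi-reference-2a}
  - {name: tectorigenin, skeleton: isoflavone, ring_a: {hydroxyl: 2, methoxyl: 1}, ring_b: {hydroxyl: 1}, provenance: quasi-reference-2a}
  - {name: orobol, skeleton: isoflavone, ring_a: {hydroxyl: 2}, ring_b: {hydroxyl: 2}, provenance: quasi-reference-2a}
  - {name: butein, skeleton: chalcone, ring_a: {hydroxyl: 1}, ring_b: {hydroxyl: 2}, provenance: quasi-reference-2a}
  - {name: pinocembrin, skeleton: flavanone, ring_a: {hydroxyl: 2}, provenance: quasi-reference-2a}
  - {name: eriodictyol, skeleton: flavanone, ring_a: {hydroxyl: 2}, ring_b: {hydroxyl: 2}, provenance: quasi-reference-2a}
  - {name: butin, skeleton: flavanone, ring_a: {hydroxyl: 1}, ring_b: {hydroxyl: 2}, provenance: quasi-reference-2a}

  # -- quasi reference standards from curated HCD spectra --------------------
  - {name: sulfuretin, skeleton: aurone, ring_a: {hydroxyl: 1}, ring_b: {hydroxyl: 2}, provenance: quasi-reference-mzCloud}
  - {name: neoflavene A, skeleton: neoflavonoid_I, ring_a: {hydroxyl: 1}, provenance: quasi-reference-mzCloud}
  - {name: neoflavene B, skeleton: neoflavonoid_I, ring_a: {hydroxyl: 1}, ring_b: {hydroxyl: 1}, provenance: quasi-reference-mzCloud}
  - {name: neoflavene C, skeleton: neoflavonoid_I, ring_a: {methoxyl: 1}, provenance: quasi-reference-mzCloud}
  - {name: neoflavene D, skeleton: neoflavonoid_I, ring_a: {methyl: 1}, provenance: quasi-reference-mzCloud}
  - {name: coumestan q1, skeleton: neoflavonoid_II, ring_a: {hydroxyl: 2}, provenance: quasi-reference-mzCloud}
  - {name: chromene q1, skeleton: neoflavonoid_III, ring_a: {hydroxyl: 1}, provenance: quasi-reference-mzCloud}
  - {name: benzochromanone q1, skeleton: neoflavonoid_IV, ring_b: {hydroxyl: 1}, provenance: quasi-reference-mzCloud}
  - {name: benzochromanone q2, skeleton: neoflavonoid_IV, ring_a: {hydroxyl: 1}, ring_b: {hydroxyl: 1}, provenance: quasi-reference-mzCloud}
  - {name: pterocarpanoid q1, skeleton: neoflavonoid_VIII, provenance: quasi-reference-mzCloud}
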