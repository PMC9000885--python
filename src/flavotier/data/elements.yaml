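# Monoisotopic masses, Da (CODATA/IUPAC 2021 values).
C: 12.0
H: 1.00782503207
O: 15.9949146196
Na: 22.9897692809
electron: 0.00054857990907
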