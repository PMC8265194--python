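# RNA/RNA Watson-Crick nearest-neighbor stacking free energies at 37 C,
# kcal/mol (Xia et al. 1998 unified parameters). Key is the 5'->3'
# dinucleotide on the target strand; the antisense strand is its exact
# complement. Duplex initiation is carried as a separate row; the default
# duplex model lumps initiation/end corrections into the structure-opening
# term, hence 0.0 here.
# version: 1
key	dG37_kcal_mol
AA	-0.93
AU	-1.10
AC	-2.24
AG	-2.08
UA	-1.33
UU	-0.93
UC	-2.35
UG	-2.11
CA	-2.11
CU	-2.08
CC	-3.26
CG	-2.36
GA	-2.35
GU	-2.24
GC	-3.42
GG	-3.26
init	0.0
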