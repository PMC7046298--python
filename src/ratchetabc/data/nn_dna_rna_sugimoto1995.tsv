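# Sugimoto 1995 RNA/DNA hybrid nearest-neighbour dG37 (kcal/mol)
# doublet = RNA strand 5'->3' (U shown as U)
doublet	dG_kcal_mol
AA	-1.01
AC	-2.09
AG	-1.81
AU	-0.89
CA	-0.91
CC	-2.10
CG	-1.69
CU	-0.89
GA	-1.31
GC	-2.70
GG	-2.91
GU	-1.10
UA	-0.60
UC	-1.50
UG	-1.59
UU	-0.21
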