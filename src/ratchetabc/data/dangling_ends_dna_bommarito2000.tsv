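# Bommarito 2000 DNA dangling-end dG37 (kcal/mol), derived from dH/dS at 310.15 K
# doublet = the dangling strand's own bases 5'->3'; end=5p: dangling,paired; end=3p: paired,dangling
doublet	end	dG_kcal_mol
AA	3p	-0.159
AA	5p	-0.513
AC	3p	0.296
AC	5p	-0.996
AG	3p	-0.037
AG	5p	-0.599
AT	3p	0.108
AT	5p	-0.543
CA	3p	-0.783
CA	5p	-0.423
CC	3p	-0.305
CC	5p	-0.492
CG	3p	0.026
CG	5p	-0.309
CT	3p	-0.548
CT	5p	-0.068
GA	3p	-0.890
GA	5p	-0.604
GC	3p	-0.169
GC	5p	-0.758
GG	3p	-0.426
GG	5p	-0.519
GT	3p	-0.337
GT	5p	0.452
TA	3p	-0.452
TA	5p	-0.697
TC	3p	-0.221
TC	5p	-0.619
TG	3p	-0.483
TG	5p	-0.620
TT	3p	-0.326
TT	5p	-0.045
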