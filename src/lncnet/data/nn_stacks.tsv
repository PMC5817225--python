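# nearest-neighbor RNA/RNA stack free energies, kcal/mol at 37C
# top: 5'->3' dinucleotide; bottom: 3'->5' dinucleotide; columns pair up
# stacks containing a G:U wobble share one moderate stabilisation term
top	bottom	dG
AA	UU	-0.93
AC	UG	-2.24
AG	UC	-2.08
AG	UU	-0.60
AU	UA	-1.10
AU	UG	-0.60
CA	GU	-2.11
CC	GG	-3.26
CG	GC	-2.36
CG	GU	-0.60
CU	GA	-2.08
CU	GG	-0.60
GA	CU	-2.35
GC	CG	-3.42
GG	CC	-3.26
GG	CU	-0.60
GU	CA	-2.24
GU	CG	-0.60
GA	UU	-0.60
GC	UG	-0.60
GG	UC	-0.60
GG	UU	-0.60
GU	UA	-0.60
GU	UG	-0.60
UA	AU	-1.33
UC	AG	-2.35
UG	AC	-2.11
UG	AU	-0.60
UU	AA	-0.93
UU	AG	-0.60
UA	GU	-0.60
UC	GG	-0.60
UG	GC	-0.60
UG	GU	-0.60
UU	GA	-0.60
UU	GG	-0.60
# duplex initiation and loop penalties
INIT	-	4.09
LOOP_OPEN	-	1.00
LOOP_PER_NT	-	0.50
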