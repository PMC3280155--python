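kmer	value
AA	-0.18
AC	-0.06
AG	0.12
AT	-0.28
CA	0.3
CC	0.13
CG	0.35
CT	0.12
GA	0.08
GC	0.25
GG	0.13
GT	-0.06
TA	0.19
TC	0.08
TG	0.3
TT	-0.18
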