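kmer	value
AA	-0.27
AC	0.45
AG	0.04
AT	-0.6
CA	0.9
CC	0.32
CG	1.3
CT	0.04
GA	0.4
GC	0.64
GG	0.32
GT	0.45
TA	-1.18
TC	0.4
TG	0.9
TT	-0.27
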