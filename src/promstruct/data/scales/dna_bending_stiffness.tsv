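kmer	value
AA	35.0
AC	60.0
AG	60.0
AT	20.0
CA	60.0
CC	130.0
CG	85.0
CT	60.0
GA	60.0
GC	85.0
GG	130.0
GT	60.0
TA	20.0
TC	60.0
TG	60.0
TT	35.0
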