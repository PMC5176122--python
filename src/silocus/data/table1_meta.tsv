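population	tm	cluster	mating_class	exclude_tm_mean
TC	0.18	1	inbreeding	no
TCA	0.48	1	inbreeding	yes
PTP	0.02	2	inbreeding	no
WAS	0.25	2	inbreeding	no
RON	0.28	2	inbreeding	no
KTT	0.31	3	inbreeding	no
LPT	0.13	4	inbreeding	no
PIN	0.84	2	outcrossing	no
OWB	0.64	5	outcrossing	no
SBD	0.94	5	outcrossing	no
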