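individual	population	srk_alleles	b80_alleles	phenotype
tc01	TC	S19	hap75,hap75	SC
tc02	TC	S19	hap75,hap75	SC
tc03	TC	S19	hap75,hap75	SC
tc04	TC	S19	hap75,hap75	SC
tc05	TC	S19	hap75,hap75	SC
tc06	TC	S19	hap75,hap75	SI
tc07	TC	S19	hap75,hap75	SC
tc08	TC	S3,S19	NA	SI
tca01	TCA	S19	hap75,hap75	SC
tca02	TCA	S19	hap75,hap75	SC
tca03	TCA	S19	hap75,hap75	SC
tca04	TCA	S19	hap75,hap75	SC
tca05	TCA	S19	hap75,hap75	SC
tca06	TCA	S19	hap75,hap75	SC
tca07	TCA	S19	hap75,hap75	SC
tca08	TCA	S19	hap75,hap75	SC
ptp01	PTP	S1	hap50,hap50	SC
ptp02	PTP	S1	hap50,hap50	SC
ptp03	PTP	S1	hap50,hap50	SC
ptp04	PTP	S1	hap50,hap50	SC
ptp05	PTP	S1	hap50,hap50	SC
ptp06	PTP	S1	hap50,hap50	SC
ptp07	PTP	S1	hap50,hap50	SC
ptp08	PTP	S1	hap50,hap43	SC
was01	WAS	S1,S19	NA	SC
was02	WAS	S1,S19	NA	SC
was03	WAS	S1,S19	NA	SC
was04	WAS	S1,S19	NA	SC
was05	WAS	S19	hap75,hap75	SC
was06	WAS	S19	hap75,hap75	SC
was07	WAS	S19	hap75,hap75	SC
was08	WAS	S19	hap75,hap75	SC
ron01	RON	S1	hap50,hap50	SC
ron02	RON	S1	hap50,hap50	SC
ron03	RON	S1	hap50,hap50	SC
ron04	RON	S1	hap50,hap50	SC
ron05	RON	S1	hap50,hap50	SC
ron06	RON	S1	hap50,hap50	SC
ron07	RON	S1	hap50,hap50	SC
ron08	RON	S1	hap50,hap50	SC
ktt01	KTT	S19	hap75,hap75	SC
ktt02	KTT	S19	hap75,hap75	SC
ktt03	KTT	S19	hap75,hap75	SC
ktt04	KTT	S19	hap75,hap75	SC
ktt05	KTT	S19	hap75,hap75	SC
ktt06	KTT	S19	hap75,hap75	SC
ktt07	KTT	S19	hap75,hap75	SC
ktt08	KTT	S19	hap75,hap75	SC
lpt01	LPT	S19	hap76,hap76	SC
lpt02	LPT	S19	hap76,hap76	SC
lpt03	LPT	S19	hap76,hap76	SC
lpt04	LPT	S19	hap76,hap76	SC
lpt05	LPT	S19	hap76,hap76	SC
lpt06	LPT	S19	hap76,hap76	SC
lpt07	LPT	S19	hap76,hap76	SC
lpt08	LPT	S19	hap76,hap99	SC
pin01	PIN	S1,S39	NA	SI
pin02	PIN	S1,S39	NA	SI
pin03	PIN	S1,S39	NA	SI
pin04	PIN	S1,S19	NA	SI
pin05	PIN	S1,S19	NA	SI
pin06	PIN	S1,S19	NA	SI
pin07	PIN	S1,S3	NA	SI
pin08	PIN	S20,S39	NA	SI
owb01	OWB	S1	hap43,hap43	SC
owb02	OWB	S1	hap43,hap43	leaky
owb03	OWB	S1	hap43,hap43	SI
owb04	OWB	S1	hap43,hap43	SC
owb05	OWB	S1	hap43,hap43	leaky
owb06	OWB	S1	hap43,hap43	SI
owb07	OWB	S1	hap43,hap43	SC
owb08	OWB	S1,S13	NA	SI
sbd01	SBD	S1	hap43,hap43	SI
sbd02	SBD	S1,S3,S45	NA	SI
sbd03	SBD	S1,S3	NA	SI
sbd04	SBD	S1,S19	NA	SI
sbd05	SBD	S1,S20	NA	SI
sbd06	SBD	S3	hap48,hapA	SI
sbd07	SBD	S3	hap48,hapA	SI
sbd08	SBD	S13	hapB,hapA	SI
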