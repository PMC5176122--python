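b80_hap	srk_alleles
hap75	S19
hap76	S19
hap50	S1
hap43	S1
hap48	S3
hap99	S27
hapA	S27
hapB	S13
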