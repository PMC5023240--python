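#=GENOME_DIFF	1.0
SNP	1	.	pCM410	2450	T
MOB	2	.	chr1	6650	ISMex25	1	3
SNP	3	.	chr1	10520	T
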