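#=GENOME_DIFF	1.0
SNP	1	.	pCM410	2410	T
MOB	2	.	chr1	1832	ISMex25	1	3
AMP	3	.	chr1	6301	300	2
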