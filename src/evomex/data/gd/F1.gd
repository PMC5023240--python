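#=GENOME_DIFF	1.0
SNP	1	.	pCM410	2400	T
MOB	2	.	chr1	1820	ISMex25	1	3
AMP	3	.	chr1	14301	231	2
SNP	4	.	chr1	18400	T
SNP	5	.	chr1	22500	T
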