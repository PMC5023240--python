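#=GENOME_DIFF	1.0
SNP	1	.	pCM410	2440	T
SNP	2	.	chr1	4050	T
SNP	3	.	chr1	10490	T
SNP	4	.	chr1	32330	T
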