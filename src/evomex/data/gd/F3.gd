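#=GENOME_DIFF	1.0
SNP	1	.	pCM410	2420	T
MOB	2	.	chr1	1844	ISMex25	1	3
SNP	3	.	chr1	6490	T
SNP	4	.	chr1	18430	T
SNP	5	.	chr1	24500	T
SNP	6	.	chr1	28400	T
SNP	7	.	chr1	32300	T
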