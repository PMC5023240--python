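#=GENOME_DIFF	1.0
SNP	1	.	pCM410	2470	T
MOB	2	.	chr1	1880	ISMex25	1	3
SNP	3	.	chr1	10550	T
AMP	4	.	chr1	14331	96	2
SNP	5	.	chr1	36430	T
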