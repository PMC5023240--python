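locus	contrast	lineage	effect	q
META1_0821	acclimation		0.0200	0.5
META1_0821	adaptation	F1	-1.1570	0.001
META1_0821	adaptation	F8	-1.0976	0.001
META2_0894	acclimation		0.0200	0.5
META2_0894	adaptation	F1	1.2690	0.001
META2_0894	adaptation	F8	1.0426	0.001
META2_0971	acclimation		0.0200	0.5
META2_0971	adaptation	F1	1.4222	0.001
META2_0971	adaptation	F8	1.2987	0.001
META1_2781	acclimation		0.0200	0.5
META1_2781	adaptation	F1	2.3702	0.001
META1_2781	adaptation	F8	2.0215	0.001
META1_1740	acclimation		0.0200	0.5
META1_1740	adaptation	F1	2.6599	0.001
META1_1740	adaptation	F8	2.5110	0.001
META1_1753	acclimation		0.0200	0.5
META1_1753	adaptation	F1	-0.8319	0.001
META1_1753	adaptation	F8	-0.9709	0.001
META1_2094	acclimation		0.0200	0.5
META1_2094	adaptation	F1	-3.0496	0.001
META1_2094	adaptation	F8	-3.0496	0.001
META1_2769	acclimation		0.0200	0.5
META1_2769	adaptation	F1	2.9203	0.001
META1_2769	adaptation	F8	2.6803	0.001
META1_2218	acclimation		0.0200	0.5
META1_2218	adaptation	F1	-1.8914	0.001
META1_2218	adaptation	F8	-1.9782	0.001
META1_0222	acclimation		1.0000	0.001
META1_0222	adaptation	F1	0.3896	0.5
META1_0222	adaptation	F8	0.1243	0.5
META1_1530	acclimation		-1.3092	0.001
META1_1530	adaptation	F1	1.1177	0.001
META1_1530	adaptation	F8	1.5008	0.001
META1_1514	acclimation		1.4950	0.001
META1_1514	adaptation	F1	-1.3391	0.001
META1_1514	adaptation	F8	-1.6508	0.001
META1_4113	acclimation		3.7752	0.001
META1_4113	adaptation	F1	-4.1803	0.001
META1_4113	adaptation	F8	-3.3702	0.001
META1_5150	acclimation		5.0699	0.001
META1_5150	adaptation	F1	-5.1599	0.001
META1_5150	adaptation	F8	-4.9800	0.001
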