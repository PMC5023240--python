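locus	lineage	category
META1_0821	F1	novel
META1_0821	F8	novel
META2_0894	F1	novel
META2_0894	F8	novel
META2_0971	F1	novel
META2_0971	F8	novel
META1_2781	F1	novel
META1_2781	F8	novel
META1_1740	F1	novel
META1_1740	F8	novel
META1_1753	F1	novel
META1_1753	F8	novel
META1_2094	F1	novel
META1_2094	F8	novel
META1_2769	F1	novel
META1_2769	F8	novel
META1_2218	F1	novel
META1_2218	F8	novel
META1_0222	F1	unrestored
META1_0222	F8	unrestored
META1_1530	F1	restored
META1_1530	F8	restored
META1_1514	F1	restored
META1_1514	F8	restored
META1_4113	F1	restored
META1_4113	F8	restored
META1_5150	F1	restored
META1_5150	F8	restored
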