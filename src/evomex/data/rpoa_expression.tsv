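gene	locus	function	category	fold_f1	fold_f8	fold_others
recO	META1_0821	DNA repair	novel	-2.23	-2.14	-1.21
dnaK	META2_0894	Hsp70 chaperone protein	novel	2.41	2.06	-1.02
polA	META2_0971	DNA polymerase	novel	2.68	2.46	1.22
META1_2781	META1_2781	putative antioxidant enzyme	novel	5.17	4.06	1.33
xoxF	META1_1740	C1 metabolism/regulation	novel	6.32	5.7	1.38
mxbD	META1_1753	C1 metabolism/regulation	novel	-1.78	-1.96	1.0
fdh4A	META1_2094	C1 metabolism	novel	-8.28	-8.28	-1.85
mauF	META1_2769	C1 metabolism	novel	7.57	6.41	1.55
gap	META1_2218	PHB biosynthesis	novel	-3.71	-3.94	-2.27
META1_0222	META1_0222	putative sensor histidine kinase	unrestored	1.31	1.09	1.79
def	META1_1530	peptide deformylase	restored	2.17	2.83	1.47
ibpA	META1_1514	heat shock protein	restored	-2.53	-3.14	-1.61
META1_4113	META1_4113	putative sarcosine oxidase-related	restored	-18.13	-10.34	-3.34
META1_5150	META1_5150	hypothetical protein	restored	-35.75	-31.56	-2.69
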