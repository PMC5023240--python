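##gff-version 3
##sequence-region chr1 1 60000
##sequence-region pCM410 1 10000
chr1	evomex	CDS	2001	2900	.	+	.	ID=icuAB;locus_tag=icuAB
chr1	evomex	CDS	6001	6900	.	+	.	ID=gshA;locus_tag=gshA
chr1	evomex	CDS	10001	10900	.	+	.	ID=kefB;locus_tag=kefB
chr1	evomex	CDS	14001	14900	.	+	.	ID=rpoA;locus_tag=rpoA
chr1	evomex	CDS	18001	18900	.	+	.	ID=META1_4902;locus_tag=META1_4902
chr1	evomex	CDS	22001	22900	.	+	.	ID=atpI;locus_tag=atpI
chr1	evomex	CDS	24001	24900	.	+	.	ID=atpF;locus_tag=atpF
chr1	evomex	CDS	28001	28900	.	+	.	ID=pntAB;locus_tag=pntAB
chr1	evomex	CDS	32001	32900	.	+	.	ID=META2_0008;locus_tag=META2_0008
chr1	evomex	CDS	36001	36900	.	+	.	ID=META1_3102;locus_tag=META1_3102
chr1	evomex	CDS	40001	40900	.	+	.	ID=mntH;locus_tag=mntH
chr1	evomex	CDS	41201	42100	.	+	.	ID=mntR;locus_tag=mntR
pCM410	evomex	CDS	1001	2200	.	+	.	ID=flhA;locus_tag=flhA
pCM410	evomex	CDS	2301	3100	.	+	.	ID=fghA;locus_tag=fghA
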