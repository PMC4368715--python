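# Strigamia maritima mitochondrial genome annotation (circular, 14983 bp).
# Coordinates are 1-based, both ends inclusive, on the plus strand.
# Printed length / codon / intergenic columns are reproduced verbatim from the
# published gene table; coordinates are authoritative where the two disagree.
gene	strand	start	end	length	start_codon	stop_codon	intergenic
cox1	+	1	1557	1557	ATT	TAA	.
cox2	+	1532	2215	684	ATG	TAG	-23
cox3	+	2221	3063	843	ATG	TAA	+5
trnG	+	3010	3058	49	.	.	-54
nad6	+	3060	3524	464	ATA	TAG	+1
nad2	+	3525	4487	963	ATT	TAA	0
trnF	-	4547	4603	57	.	.	+61
nad5	-	4606	6306	1701	ATG	TAG	+2
trnH	-	6287	6347	61	.	.	-20
nad4	-	6348	7664	1317	ATG	TAA	0
nad4l	-	7658	7921	264	ATT	TAA	-8
trnP	-	7909	7972	64	.	.	-13
NC1	.	7973	8414	442	.	.	0
trnD	+	8415	8489	75	.	.	0
atp8	+	8461	8622	162	ATA	TAA	-29
atp6	+	8616	9281	666	ATG	TAA	-7
trnR	+	9331	9375	45	.	.	+49
trnE	+	9409	9454	46	.	.	+33
trnT	+	9455	9506	52	.	.	0
cob	+	9508	10641	1134	ATC	TAG	+1
trnM	+	10652	10710	59	.	.	+10
trnI	+	10706	10759	54	.	.	-5
trnY	-	10765	10825	61	.	.	+5
trnV	-	10880	10937	58	.	.	+55
NC2	.	10938	11331	394	.	.	0
trnS2	+	11332	11387	56	.	.	0
nad3	+	11382	11732	351	ATT	TAA	-6
trnN	+	11752	11799	48	.	.	+19
trnK	-	11831	11888	58	.	.	+31
nad1	-	11942	12862	921	ATT	TAG	+52
rrnL	-	12888	14258	1371	.	.	+24
trnL2	+	14078	14148	71	.	.	-181
rrnS	-	14111	14850	740	.	.	-38
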