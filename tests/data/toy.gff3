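##gff-version 3
chr1	lncsynt	gene	101	200	.	+	.	ID=pcA;biotype=protein_coding
chr1	lncsynt	transcript	101	200	.	+	.	ID=pcA.t1;Parent=pcA
chr1	lncsynt	exon	101	150	.	+	.	ID=pcA.t1.exon1;Parent=pcA.t1
chr1	lncsynt	exon	161	200	.	+	.	ID=pcA.t1.exon2;Parent=pcA.t1
chr1	lncsynt	gene	301	400	.	-	.	ID=pcB;biotype=protein_coding
chr1	lncsynt	transcript	301	400	.	-	.	ID=pcB.t1;Parent=pcB
chr1	lncsynt	exon	301	400	.	-	.	ID=pcB.t1.exon1;Parent=pcB.t1
chr1	lncsynt	gene	451	600	.	+	.	ID=lncL;biotype=lncRNA
chr1	lncsynt	transcript	451	600	.	+	.	ID=lncL.t1;Parent=lncL
chr1	lncsynt	exon	451	500	.	+	.	ID=lncL.t1.exon1;Parent=lncL.t1
chr1	lncsynt	exon	551	600	.	+	.	ID=lncL.t1.exon2;Parent=lncL.t1
chr1	lncsynt	gene	1001	1100	.	+	.	ID=pcC;biotype=protein_coding
chr1	lncsynt	transcript	1001	1100	.	+	.	ID=pcC.t1;Parent=pcC
chr1	lncsynt	exon	1001	1100	.	+	.	ID=pcC.t1.exon1;Parent=pcC.t1
chr2	lncsynt	gene	51	150	.	+	.	ID=miscX;biotype=other
chr2	lncsynt	transcript	51	150	.	+	.	ID=miscX.t1;Parent=miscX
chr2	lncsynt	exon	51	150	.	+	.	ID=miscX.t1.exon1;Parent=miscX.t1
chr2	lncsynt	gene	501	900	.	-	.	ID=lncM;biotype=lncRNA
chr2	lncsynt	transcript	501	900	.	-	.	ID=lncM.t1;Parent=lncM
chr2	lncsynt	exon	501	600	.	-	.	ID=lncM.t1.exon1;Parent=lncM.t1
chr2	lncsynt	exon	701	800	.	-	.	ID=lncM.t1.exon2;Parent=lncM.t1
chr2	lncsynt	exon	851	900	.	-	.	ID=lncM.t1.exon3;Parent=lncM.t1
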