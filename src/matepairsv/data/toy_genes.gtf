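chr10	toy	exon	45501	46000	.	-	.	gene_name "FGFR2"; transcript_id "IIIb";
chr10	toy	exon	44001	44500	.	-	.	gene_name "FGFR2"; transcript_id "IIIb";
chr10	toy	exon	43001	43300	.	-	.	gene_name "FGFR2"; transcript_id "IIIb";
chr10	toy	exon	41501	42000	.	-	.	gene_name "FGFR2"; transcript_id "IIIb";
chr10	toy	exon	40001	40500	.	-	.	gene_name "FGFR2"; transcript_id "IIIb";
chr10	toy	exon	45501	46000	.	-	.	gene_name "FGFR2"; transcript_id "IIIc";
chr10	toy	exon	44001	44500	.	-	.	gene_name "FGFR2"; transcript_id "IIIc";
chr10	toy	exon	42501	42800	.	-	.	gene_name "FGFR2"; transcript_id "IIIc";
chr10	toy	exon	41501	42000	.	-	.	gene_name "FGFR2"; transcript_id "IIIc";
chr10	toy	exon	40001	40500	.	-	.	gene_name "FGFR2"; transcript_id "IIIc";
chr10	toy	exon	10001	10400	.	+	.	gene_name "MGEA5"; transcript_id "MGEA5-001";
chr10	toy	exon	11501	11900	.	+	.	gene_name "MGEA5"; transcript_id "MGEA5-001";
chr10	toy	exon	13001	13500	.	+	.	gene_name "MGEA5"; transcript_id "MGEA5-001";
chr10	toy	exon	14501	15000	.	+	.	gene_name "MGEA5"; transcript_id "MGEA5-001";
chr10	toy	exon	20001	20300	.	+	.	gene_name "BICC1"; transcript_id "BICC1-001";
chr10	toy	exon	21501	21900	.	+	.	gene_name "BICC1"; transcript_id "BICC1-001";
chr10	toy	exon	23001	23400	.	+	.	gene_name "BICC1"; transcript_id "BICC1-001";
chr10	toy	exon	25501	26000	.	+	.	gene_name "BICC1"; transcript_id "BICC1-001";
chr4	toy	exon	5001	5300	.	+	.	gene_name "TACC3"; transcript_id "TACC3-001";
chr4	toy	exon	6501	6900	.	+	.	gene_name "TACC3"; transcript_id "TACC3-001";
chr4	toy	exon	8001	8400	.	+	.	gene_name "TACC3"; transcript_id "TACC3-001";
chr4	toy	exon	9501	10000	.	+	.	gene_name "TACC3"; transcript_id "TACC3-001";
chr4	toy	exon	24001	24500	.	+	.	gene_name "ERRFI1"; transcript_id "ERRFI1-001";
chr4	toy	exon	25501	26000	.	+	.	gene_name "ERRFI1"; transcript_id "ERRFI1-001";
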