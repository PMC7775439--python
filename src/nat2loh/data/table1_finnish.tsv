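# Finnish colorectal cancer cohort (SNP-array genotyping, 1511 haplotyped
# tumor/normal pairs): per-genotype counts of individuals, LOH events and
# events where the rapid *4 allele was the one lost.
genotype	individuals	loh_events	rapid_losses
*4/*4	117	1	1
*4/*12A	2	2	1
*4/*5A	20	4	2
*4/*5B	328	95	50
*4/*5C	16	6	3
*4/*6A	170	58	29
*4/*7B	30	11	8
*5A/*5A	1	0	0
*5B/*5B	228	12	0
*5C/*5C	3	0	0
*5A/*5B	33	15	0
*5A/*5C	6	3	0
*5B/*5C	35	16	0
*5A/*6A	20	6	0
*5B/*6A	308	106	0
*5C/*6A	19	5	0
*5A/*7B	5	2	0
*5B/*7B	58	15	0
*5C/*7B	1	1	0
*6A/*6A	84	0	0
*6A/*7B	25	9	0
*7B/*7B	2	0	0
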