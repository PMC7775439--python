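# Swedish colorectal cancer cohort (90x whole-genome sequencing, 56 tumor/normal
# pairs): per-genotype counts of individuals, LOH events and events where the
# rapid *4 allele was the one lost.
genotype	individuals	loh_events	rapid_losses
*4/*4	2	0	0
*4/*5A	1	0	0
*4/*5B	10	4	0
*4/*5C	1	1	1
*4/*6A	5	0	0
*4/*7B	1	0	0
*5B/*5B	6	0	0
*5B/*5C	3	0	0
*5A/*6A	1	0	0
*5B/*6A	18	0	0
*5B/*7B	3	0	0
*6A/*6A	4	0	0
*6A/*7B	1	0	0
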