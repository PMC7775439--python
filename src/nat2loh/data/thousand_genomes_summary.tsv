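# Published global NAT2 slow-allele statistics from the phased haplotypes of
# 2054 individuals (1000 Genomes Phase 3): per-group allele frequency, fraction
# of individuals heterozygous for the group, and fraction heterozygous with a
# rapid (*4 or *12) allele on the other haplotype. Percent units.
group	allele_freq_pct	het_any_pct	het_with_rapid_pct
*5	29.3	35.7	15.1
*6	26.5	36.7	13.4
*7	7.7	13.0	5.7
*14	2.8	5.0	1.6
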