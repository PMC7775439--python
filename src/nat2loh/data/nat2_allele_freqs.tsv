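# Nominal global per-allele frequencies used as the default diplotype prior for
# imputation and as the default simulation frequency map. Group sums approximate
# the 1000 Genomes global group frequencies (*5 29.3%, *6 26.5%, *7 7.7%, *14 2.8%).
allele	frequency
*4	0.332
*5A	0.030
*5B	0.220
*5C	0.030
*5D	0.008
*6A	0.260
*7B	0.075
*12A	0.005
*14A	0.025
*14B	0.015
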