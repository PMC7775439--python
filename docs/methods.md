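# Methods

This note records the models, parameter choices and limitations behind
`nat2loh`, in the order data flows through the package.

## Star-allele definitions as data

The allele table ships as an editable TSV rather than code, because
nomenclature is data: each star allele is a set of (rsid, alternate-base)
pairs over the seven classifying coding SNPs, and classification is an
exact-match lookup over that set.  The packaged table is deliberately
restricted to the alleles observed in the cohorts this tool was built
around (\*4, \*5A, \*5B, \*5C, \*6A, \*7B, \*12A) plus \*14A/\*14B and the
341T>C-only allele \*5D from the consensus nomenclature — a compact
universe keeps diplotype imputation ambiguity interpretable, and users can
extend the TSV.  Patterns that match no row are returned as
`UnclassifiedPattern`, never silently dropped, so novel alleles (e.g. a
wild-type haplotype carrying the rare synonymous rs144176822) stay visible;
rs144176822 is catalogued as an auxiliary annotation, not a classifying
site, because it does not change the protein.

Coordinates: genomic positions are 1-based GRCh38; CDS positions 1-based on
the coding strand; interval arithmetic is half-open internally.  The
classifying sites and rs144176822 sit at their true chr8 coordinates
(genomic = 18400003 + CDS position).  The packaged 2096 bp amplicon FASTA
is a **synthetic stand-in** (its filename and header say so): the base at
every catalogued site offset is the true reference base, but the sequence
between sites is generated, and the six auxiliary LOH-marker SNPs (rs2552,
rs4646247, rs971473, rs45547533, rs721398, rs721399) are placed at nominal
flank coordinates — they function purely as heterozygous markers for
imbalance, so only their existence and het status matter to the pipeline.
Analyses of real reads should swap in the true amplicon sequence via
`--reference`; all coordinates and logic are unchanged by that swap.

## Long-read haplotyping

Reads carry a sample-unique 15 bp barcode plus 5 bp padding on both
primers.  Demultiplexing matches read ends against barcodes at a default
tolerance of one mismatch per 15-mer (not specified by the assay; one
mismatch accepts virtually all CCS-grade reads while keeping the expected
cross-assignment probability negligible for random barcode sets).
Equal-distance ties between samples, and disagreement between the two ends
when both carry a recognizable barcode, leave a read unassigned.
Assignment is invariant under reverse-complementing the read.

The length filter retains reads of 1500–2300 nt inclusive (the window is a
property of the assay; inclusivity is this package's choice, exposed via
`--lo/--hi`).  Alignment is semi-global — the read is located as an infix
of the amplicon, end-gaps on the reference free — with unit edit costs via
edlib, forward orientation preferred on score ties.  Unit costs rather
than an affine-gap scheme is a deliberate trade: for a single 2 kb
amplicon at CCS-like error rates the optimal unit-cost alignment recovers
the same bases at the catalogued sites, and edlib's bit-parallel kernel
keeps a 200-replicate simulation study in tens of seconds.  Reads whose
alignment identity (1 − distance/columns) falls below 0.8 are marked
unaligned.  Externally aligned SAM/BAM is accepted as an alternative input
path (`observations_from_sam`).

Diploid calling uses only reads with non-gap base calls at all seven
classifying sites ("spanning reads"); a gap at a classifying site excludes
the read rather than imputing a deleted base.  Classes are ranked by
support; the runner-up is accepted as a second allele iff its fraction is
≥ 0.20 of spanning reads **and** its count is ≥ 5; fewer than 20 spanning
reads is a no-call.  These thresholds are package defaults chosen so that
both realistic low-coverage scenarios — ~150 spanning reads of a single
class (homozygote) and a two-class sample at ~240× — call correctly with
wide margins; the assay itself states no thresholds.  A homozygous call
below 100 spanning reads is annotated "second allele not excluded", since
allele dropout cannot be excluded at low coverage.  If the modal
unclassified pattern reaches 20% of spanning reads the call is flagged as
a novel-allele candidate.

Stage accounting is conserved and logged on every run:
total = assigned + unassigned; assigned = length-pass + length-fail;
length-pass = aligned + unaligned.

## Imputation from unphased genotypes

Candidates are enumerated exhaustively over unordered pairs from the
allele table; a pair is consistent iff its combined alternate multiplicity
(0/1/2) matches the genotype at every classifying site.  Missing
classifying-site genotypes block imputation (the "informative calls"
requirement); missing auxiliary sites never do.  Ambiguity — classically,
heterozygosity at 341+481+803 fitting both \*4/\*5B and \*5A/\*12A — is
resolved by the product of population allele frequencies (a diplotype
prior), with ties broken by natural allele-name order and flagged, and the
full candidate list always reported for audit.  The packaged per-allele
frequency table is a nominal default whose group sums approximate the
global slow-group frequencies (29.3/26.5/7.7/2.8% for \*5/\*6/\*7/\*14);
per-allele splits are not published, so the table is explicitly editable
and the resolver falls back to a flagged uniform prior when a frequency is
missing.

## LOH calling

Only sites heterozygous in the matched normal are informative; the B
allele is defined as the alternate base (the array A/B convention being
platform-specific).  LOH is called when |tumor − normal| allelic fraction
≥ 0.10 at **one or more** informative sites — an ANY-site rule, with
directional consistency across suprathreshold sites reported as a
diagnostic, never enforced.  The same absolute-fraction rule serves BAF
mode, read-count mode and long-read allele-class mode; the WGS "10% shift"
rule is read as an absolute fraction shift, mirroring the array rule.  The
threshold comparison is inclusive and guarded by a 1e-9 epsilon so that
binary-float artifacts (0.50 − 0.40 < 0.10 in doubles) cannot flip a
boundary case.  "No informative sites" is a distinct no-call, never "no
LOH".

The lost allele is identified by majority vote over informative markers:
an alternate-fraction decrease votes for the alternate-carrying haplotype
(phase taken from the called diplotype, or supplied for auxiliary
markers); a tied vote returns unknown with a conflict flag.  No tumor
purity correction is applied to calls — purity enters only the simulation
and the detectability analysis: under hemizygous one-copy loss at purity
p, the lost allele's expected tumor BAF is (1−p)/(2−p), so detection at
threshold t requires p ≥ 2t/(0.5+t), i.e. purity 1/3 at t = 0.10.

## Eligibility and cohort summaries

Eligibility requires, in order: resolved normal diplotype; intermediate
phenotype; LOH; rapid allele lost; retained slow allele APA-sensitive
(groups \*5/\*6/\*14, not \*7).  The reason code records the first failing
condition; an LOH event whose lost allele cannot be determined fails the
"rapid allele lost" condition (reason `slow-allele-lost`), a conservative
reading that never promotes uncertain events to eligible.

Cohort summaries key genotype rows by unordered pair with the rapid allele
first (\*4/\*6A, not \*6A/\*4).  Every derived percentage is a ratio of
integer count fields, rounded half-up to one decimal (integer where
convention prints integers); the test suite recomputes each ratio
independently.  The eligible-population estimator is a plain product of
user-supplied factors (incidence × targetable-intermediate fraction × LOH
fraction × optional rapid-loss fraction) with each factor echoed in the
output.  It deliberately hard-codes nothing: the published ~79,000/year
figure is not reconstructible from the headline factors alone
(1.3e6 × 0.358 × 0.21 = 97,734), as it was built from per-population
weighting whose composition is not in the main text — so the estimator
reports whatever its inputs imply and leaves sourcing to the caller.

## Synthetic data: what it emulates, and what it does not

The generator produces Hardy-Weinberg populations (two independent allele
draws per individual), tumor/normal pairs with clonal hemizygous loss, and
the two measurement modalities.  Defaults are the study conditions:
LOH probability 0.243 (the overall locus LOH rate in the larger cohort),
p(rapid lost | LOH, heterozygote) = 0.5 (near-even observed loss
direction), tumor purity 0.6 (cohorts required > 40% tumor cell content),
coverage 100×, substitution rate 1% and indel rate 0.5% (CCS-like),
read-length jitter truncated-normal around the 2096 bp amplicon with sd
300 and bounds [0.6, 1.1] × amplicon (so a realistic minority of reads
fails the 1500–2300 filter), BAF noise sd 0.05 (half the 0.10 threshold,
which corresponds to one normal-sample standard deviation), and auxiliary
markers heterozygous with probability 0.45.  All randomness flows from a
single integer seed through `numpy.random.default_rng`; identical seeds
give byte-identical outputs.

Not modelled, hence not demonstrated by passing tests: copy-neutral LOH
and reference-copy gains (the BAF model assumes pure one-copy loss),
subclonal LOH mixtures (single clonal fraction = purity), PacBio
polymerase-pass quality structure (errors are uniform substitutions plus
geometric-length indels), chimeric reads, PCR/sequencing allele bias, and
population LD beyond Hardy-Weinberg pairing.  Results on real data depend
on those factors; the simulation studies validate the calling logic, not
instrument physics.

## Problem sizes used in validation

The round-trip study runs 200 replicates at 50× coverage (1%/0.5% errors)
and requires ≥ 99% exact diplotype recovery; the purity boundary scan uses
a 0.02-step grid over (0, 1]; cohort statistics are exact integer
arithmetic on the packaged count tables; Hardy-Weinberg and LOH-rate
recovery are checked at n = 2,000–10,000 within three binomial standard
errors.
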