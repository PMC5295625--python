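# Methods

## Problem setting

`poolvar` curates variant calls from pooled targeted resequencing: DNA from
~200 diploid individuals is combined into each of ~8 pools, PCR amplicons of
~600 bp over candidate genes are sequenced to depths of order 10⁴ per pool,
and several discovery pipelines (aligner × caller combinations) emit VCFs.
Because samples are pooled, read counts — not genotypes — carry the signal: a
variant carried heterozygously by a single sample has a within-pool allele
frequency of 1/(2N) (0.0025 for N = 200), so at depth d it is supported by
only d/(2N) reads and must be separated from sequencing errors of comparable
magnitude. The package implements the five-stage workflow around this
problem: region QC, multi-caller merging, pooled allele counting, the
error-ratio filter cascade, and consequence annotation, plus a synthetic
generator that reproduces the data-generating process for validation.

## Fragment assignment and capture QC

A fragment is assigned to a primer-defined target region only under
reciprocal overlap: the overlap must cover ≥ 90% of the fragment *and*
≥ 90% of the region. The boundary is inclusive and evaluated with exact
rational arithmetic, so an overlap of exactly 540/600 qualifies. When two
regions qualify (overlapping amplicons), the one with the larger product of
the two overlap fractions wins; an exact tie yields no assignment, keeping
assignment a deterministic partial function. Fragments that are not
properly paired or not uniquely mapped are never assigned but stay in the
capture-rate denominator. Coordinates are 1-based inclusive internally;
BED I/O converts at the boundary. (Region, pool) pairs with fewer than 20
assigned fragments (strictly) are flagged as low-coverage. The
`coverage_gap` helper quantifies the uncovered amplicon center left by read
trimming: max(0, amplicon − read1 − read2), e.g. 190 bp for a 600 bp
amplicon read as 240 + 170 bp.

## Callset merging and normalization

Alleles are matched across callers on (chrom, pos, ref, alt) after
normalization: multi-allelic records are split, shared terminal bases are
trimmed with left extension from the reference whenever an allele would
empty (the standard left-alignment loop), and shared leading bases are then
trimmed. Without this, equivalent indel representations from seven callers
would inflate the union. Alleles meeting at a locus are re-fused into one
site, padding shorter REF alleles against the longest; a locus biallelic in
each caller but with different alternatives across callers therefore
becomes multiallelic in the merged set. Classification into biallelic SNP /
biallelic indel / multiallelic always partitions the union. Provenance (the
pipeline set per site) feeds per-pipeline, pairwise, and exactly-k-pipeline
intersection summaries, Jaccard consistency of a caller between its two
aligners, and overlap with an external reference callset, optionally
stratified by caller-reported MAF. The reader tolerates unknown header
fields (one consumed caller format is dated); REF disagreement with the
reference FASTA is a hard error naming the record.

## Pooled counting and frequency estimation

At SNP sites the counter records the base observed per read at the position,
excluding base calls below Phred 20 by default — no threshold is inherent to
the method, but a standard cutoff prevents trim-end errors from dominating.
At indel sites a read must span the reference interval plus one anchor base
and match the ref or alt allele exactly; soft-clipped or non-spanning reads
are ignored (conservative and testable). Raw frequency is count/total
depth. The *adjusted* frequency is alt/(ref + alt): error-allele reads are
excluded from the denominator, so it is ≥ the raw alt frequency and equal
when no error reads exist. Zero-depth (or zero ref+alt) pools report a
missing value rather than zero so cross-pool ranges are not deflated; the
cross-pool range (max − min of adjusted frequencies) is flagged at 0.05 and
0.1 and requires at least two informative pools.

## The error-ratio filter cascade

The error statistic at a SNP site is the mean of the two smallest of the
four nucleotide read counts (ranks 3–4 with counts sorted descending, ties
broken lexicographically). The site's error ratio is the second-ranked
count over this estimate; sites with ratio < 5 are rejected — their minor
support is indistinguishable from the error floor. Degenerate cases: a
zero error estimate with positive minor support gives +inf (passes); zero
over zero gives 0 (a site with no minor support is not a variant). The
full cascade runs, in order: (1) remove SNPs embedded in the reference span
of any indel in the set; (2) keep biallelic SNPs only; (3) total read depth
(summed across pools by default) ≥ 10,000; (4) alt reads ≥ 1 in ≥ 2 pools;
(5) error ratio ≥ 5. Both the depth filter and the error statistic can be
switched to per-pool-any aggregation in `FilterConfig`; "presence" of a
variant in a pool is defined by a configurable minimum alt read count
(default 1). Each stage's attrition is reported and the stages chain
exactly; the cascade is idempotent, and tightening any threshold can only
shrink the output.

## Consequence annotation

Coding SNPs are classified by translating the reference and alternative
codon (standard nuclear code; reverse complement on minus-strand
transcripts; frame from CDS phase, with the phase of the first CDS segment
in translation order as the reading offset): synonymous, missense, nonsense
(stop gained) or stop lost. Coding indels are frameshift when the net
length change is not a multiple of three, otherwise in-frame
deletion/insertion with the affected residue named. SNPs inside a gene but
outside its CDS — true introns and untranslated exon portions alike — are
reported as intron; splice-site classes are not modelled. Variants in the
partial leading codon implied by a nonzero phase are also reported as
intron rather than guessed. The most-severe summary uses the fixed order
frameshift > nonsense > stop_lost > missense > in-frame > synonymous >
intron > intergenic; with several transcripts per gene all are annotated
and the gene summary takes the most severe. Per-gene density is coding
variants × 1000 / covered exonic bp; `genome_snp_density` is the plain
ratio of surveyed bp to variant count.

## Synthetic data model

`simulate_pools` draws, per site, a population frequency from a mixture
spectrum (default: 65% rare sites uniform on [1/400, 0.01], the rest
uniform on [0.01, 0.5], echoing the dominance of rare alleles in germplasm
pools); per pool, carrier alt copies ~ Binomial(2N, f) give the true pool
fraction; reads are one multinomial per (site, pool) over the four bases,
with each read independently corrupted to a uniform other base with
probability 0.002 by default (sequencers are not uniform, but the rate is
the quantity the filter sees; it is configurable). Counts are generated
directly — they are the sufficient statistic for every downstream stage —
so no FASTQ-level artefacts (strand bias, position-dependent error,
PCR duplicates, population structure between pools) are represented:
passing tests validate the counting, filtering and frequency mathematics,
not robustness to those real-data effects. `simulate_fragments` covers the
QC path with a planted on-target fraction (on-target fragments jittered
within the reciprocal-overlap margin; off-target ones in inter-region gaps
or flagged improper/multimapping). `simulate_callsets` writes one VCF per
pipeline profile: a profile calls a true site iff its largest per-pool MAF
reaches the profile's detection floor, plus Poisson false positives at
random non-variant positions; the default 12-profile roster mirrors a
2-aligner × 7-caller design in which the pool-aware callers have the lowest
floors and two callers run from one aligner only. The bundle also emits
pure-error read counts at the false-positive positions (re-genotyping a
noise-driven call yields error-level counts) and toy single-exon gene
models so annotation can run end to end. All outputs are byte-identical
given the same seed; independent streams are derived per component from the
one configured seed.

`detection_power` plants one site per replicate at a chosen population
frequency, simulates the pools, runs the full cascade and reports the
surviving fraction with its binomial standard error. Note the error-ratio
statistic's expectation is roughly 3f/e + 1 independent of depth, so power
rises with depth only where that expectation clears the threshold; near the
boundary (f ≈ e·(threshold−1)/3) power is intrinsically unstable in depth.

## Numerical and testing choices

Overlap fractions use exact `Fraction` arithmetic so the 90% boundary and
tie detection are not float-sensitive. Frequency-recovery validation
compares adjusted frequencies with true pool fractions at a 4·√(f(1−f)/d)
tolerance over pools with at least one carrier (at f = 0 the tolerance is
zero while errors contribute a small positive estimate; the zero-carrier
case is instead checked exactly under a zero error rate). Default test and
validation problem sizes — up to 1000 sites × 8 pools at depths 2,000–20,000
and 10–20 regions — were chosen so every suite completes in seconds while
keeping Monte-Carlo error far from the asserted margins. Filter-cascade
validation at 20,000× aggregate depth measured ≥ 95% rejection of
pure-error sites and ≥ 95% retention of planted MAF 0.01 sites at
threshold 5, matching the design intent of the ratio filter.

## Known limitations

Individual genotypes cannot be recovered from pools; the package never
attempts it. Indel counting requires exact span matches and will undercount
in noisy alignments. The merge may unify indel representations that
upstream callers counted as distinct sites — deliberate, but it means raw
union counts are not comparable with tools that skip normalization. The
error model is substitution-only; indel sequencing errors are not
simulated. UTR variants are folded into the intron class.
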