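# Methods

## Problem and model

RNA editing by ADAR converts adenosine to inosine within double-stranded
RNA; inosine base-pairs like guanosine, so an edited position appears as an
A→G mismatch between a genomic DNA sample and cDNA reads from the same
individual. Detection therefore reduces to comparing, at each pileup
position, a genomic genotype call against per-tissue cDNA allele counts,
with strand resolution so that A-to-G events on minus-strand transcripts
(genomic T→C) are not misread as T-to-C.

The unit of analysis is the (site, tissue) pair: a site edited in two
tissues contributes two candidate events, which is also how the per-tissue
summary tables count.

### Inputs

Two multi-sample VCFs produced by an mpileup-style caller — one from
plus-strand transcript alignments, one from minus-strand — with the genomic
DNA sample in the first sample column and one cDNA sample per tissue after
it. Required fields: per-sample `DP` (depth), `DV` (high-quality
non-reference read count, aggregate over alternate alleles), `SP`
(phred-scaled strand-bias P-value), and site-level `INFO MQ` (RMS mapping
quality) and `INFO INDEL`. Upstream of variant calling, alignment streams
are reduced to uniquely mapped reads by tag predicates: genomic reads
carrying an integer `XS` tag (alternative-alignment count) are dropped;
cDNA reads are kept when `NH:i:1` and split by transcript strand on
`XS:A:+` / `XS:A:-`. These filters are implemented at the SAM text level
because they are pure tag predicates; no CIGAR or sequence interpretation
is needed.

### Candidate criteria

A mismatch is accepted when, jointly:

1. homozygous genotype: the majority allele carries ≥ 95% of DNA reads
   (`homozygosity_fraction`, boundary inclusive on both the reference and
   alternate side);
2. genotype depth: DNA `DP` ≥ 10 (`min_dna_depth`);
3. no indel: the `INDEL` flag is absent and all alleles are single bases;
4. edited support: ≥ 5 cDNA reads differ from the genotype call
   (`min_edited_reads`) — `DV` at homozygous-reference loci, `DP − DV` at
   homozygous-alternate loci, the only reading consistent with an
   aggregate `DV`;
5. strand balance: the tissue's `SP` ≤ 20 (`max_strand_bias_phred`),
   evaluated per tissue, since candidates are per-tissue events.

Sites with more than one non-missing alternate allele are excluded
(counted separately): an aggregate `DV` cannot attribute reads to a
specific allele. Missing `DV`/`SP` in a cDNA sample excludes that tissue at
that site (fail closed). Heterozygous loci are out of scope by design: at a
het site one cannot tell which allele would be edited.

All thresholds live in `DetectionParams`; raising any of them can only
shrink the candidate set (tested as a monotonicity property).

### Mapping-error significance

Under the null of no editing, apparent edited reads are mis-mapped reads.
With phred mapping quality MQ, the per-read error probability is
p = 10^(−MQ/10), and the probability of observing at least k edited reads
among depth N is the binomial upper tail P(X ≥ k | N, p). The
implementation evaluates the survival function (regularised incomplete
beta via scipy) rather than the complement of the partial sum, because for
tails of order 1e-12 the textbook form 1 − Σ_{j<k} loses all relative
precision to cancellation. Accuracy is verified against an exact
rational-arithmetic summation to ≤ 1e-12 relative error over
n ≤ 200, k ≤ 10 and p from 1e-6 to 0.5. Transcriptome-wide significance
uses Bonferroni: threshold α/m, where m counts queried cDNA positions —
(site, tissue) pairs at homozygous, non-indel, depth-sufficient loci with
cDNA depth ≥ 5 — implemented literally as the division, with a helper to
count m from the VCF pair. k defaults to `min_edited_reads` so the model
stays coupled to criterion 4.

### Annotation

Repeat overlap uses per-chromosome lists of RepeatMasker intervals sorted
by begin; lookup is a binary search on interval starts followed by a
backward scan bounded by the longest interval on the chromosome, so nested
and long-spanning earlier intervals are still found. Both VCF positions and
RepeatMasker intervals are 1-based with inclusive ends; containment is
positional only (repeat strand is ignored). When several intervals contain
a position, the one with the largest begin (innermost start) wins — a
deterministic rule chosen because nesting is rare and no principled
alternative presents itself. Equivalence with a naive linear scan under the
same tie rule is property-tested on random nested/abutting instances.

VEP merging keys on (chrom, pos, genomic variant allele). VEP emits one row
per overlapping transcript; the retained row is the one whose consequence
has the highest priority in the fixed order missense/stop/start >
synonymous > UTRs > intron > non-coding transcript > upstream/downstream >
intergenic, ties broken by gene then feature identifier. Candidates with no
matching row keep category `other`. Categorisation is a total function:
every candidate gets exactly one location category, and merging never
changes the candidate count.

### Summaries

Four surfaces: per-tissue counts over the 12 ordered mismatch types (all
candidates vs those inside repeats), cross-tissue sharing as exact Venn
cells over (chrom, pos, strand) — same position but opposite strand is
never shared —, repeat family/element distributions with shares out of all
repetitive A-to-G events, and genic location distributions. Percentages are
rounded half-even to one decimal. Conservation (cells and counts sum to the
relevant totals) and permutation invariance are tested properties.

## Synthetic data

`synthetic.generate_fixture` writes the exact formats the pipeline reads
(paired VCFs, RepeatMasker `.out`, VEP tabular output) plus truth tables,
deterministically from one seed. Default conditions: 1000 sites, 200
planted edits across 3 tissues (labels Liver/Fat/LD), DNA depth 10–60,
cDNA depth 8–60, edited fraction 0.1–0.9, half the edits on the minus
strand (written as genomic T→C), 20% at homozygous-alternate loci, site MQ
20–60, and 60% of edit sites covered by generated repeat intervals whose
name mix (60% Pre0_SS, PRE-1 variants, L1, LTR, tRNA) is allocated exactly
by largest remainder. Honest sites draw SP uniformly in [0, 20];
strand-bias confounders in [21, 60]. Six confounder classes at 6% of sites
each are constructed to fail exactly one exclusion: heterozygous (criterion
1), DNA depth ≤ 9 (criterion 2), indel (criterion 3), 1–4 edited reads
(criterion 4), SP > 20 (criterion 5), and multiallelic. Positions sit on a
1 kb lattice so repeat intervals (half-width ≤ 300 bp) can never capture a
neighbouring site; no sequence is modelled because detection is
allele-level.

What passing on fixtures shows — and does not. The generator plants
unambiguous truth, so exact recovery demonstrates that the filter logic,
strand handling and annotation joins are correct. It does not emulate
base-calling error, alignment artefacts around splice junctions, allele-
specific expression, or realistic editing-rate biology, so fixture results
say nothing about sensitivity/specificity on real reads; real-data
headline counts are not reproducible at desk scale and are out of scope.

## Numerical and design notes

- VCF parsing retains raw columns, so the paired writer re-emits files
  byte-identically; parse errors name the offending line. Gzip input is
  detected by magic bytes. The reader is cross-checked against
  pysam/htslib on a generated fixture.
- Binomial tails below ~1e-300 underflow to 0, which is acceptable for
  any practical threshold.
- Output ordering is everywhere deterministic — candidates by (chrom, pos,
  strand, tissue) with natural chromosome order — and intermediate tables
  carry a schema-version header line for exact-diff regression testing.
- SIFT text from VEP's `Extra` column is normalised from
  `deleterious(0.02)` to `deleterious (0.02)` for reporting; the raw text
  is preserved for round-trips.
- The worked mapping-error value for N = 13, MQ = 29 is 4.0358e-12 by
  exact summation of the tail formula (the single-term approximation
  C(13,5)p⁵ without the (1−p)⁸ factor gives the slightly larger 4.07e-12).

## Known limitations

- Heterozygous-site editing and editing-level quantification (fractions
  with confidence intervals) are not attempted.
- Multiallelic sites are dropped rather than resolved; with an
  allele-resolved caller (`AD`-style tags) they could be retained.
- VEP consequence vocabulary outside the mapped terms falls into `other`.
- The Bonferroni helper counts tests from the VCF pair presented to it;
  if detection and counting use different input subsets, m must be
  supplied explicitly.
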