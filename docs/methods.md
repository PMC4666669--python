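# Methods

## Overview

`clipsv` is a joint multi-sample structural-variant (SV) caller for
paired-end short-read alignments with standard insert sizes (~300–500 bp),
together with an association test, a post-hoc SV-type classifier, a
synthetic evidence generator and a truth-interval benchmark harness.  The
caller works from mapping signals alone — soft/hard clipping, split-read
(SA) and alternative (XA) alignments, mate-pair geometry and a clip
consensus — and makes no use of assembly.

All internal coordinates are 0-based, half-open.  The single conversion to
1-based coordinates happens in the VCF writer; the single conversion from
1-based tag positions happens in the SA/XA parser.

## Breakpoint detection

Reads from every BAM are pooled into one index that hashes each clip
boundary by exact (contig, position, side).  Unmapped and duplicate-flagged
records are excluded (duplicates are a classic source of spurious shared
clips); secondary/supplementary records contribute sequence and split-read
evidence but not support.  A position becomes a candidate when at least
`min_support` (default 3) primary clipped reads share the boundary.

The clipped overhangs of a candidate are collapsed by anchor-aligned column
majority voting: all clips of one candidate share a physical anchor (the
breakpoint), so right clips are left-aligned at the anchor, left clips
right-aligned, padded to the longest, and each column takes its majority
base (ties to the lexicographically smallest base, for reproducibility).
This replaces a gapped multiple sequence alignment; with a fixed shared
anchor a gapped MSA adds little, and the column-majority form is
deterministic and O(n·L).  The mismatch fraction is the share of non-pad
characters disagreeing with their column's consensus; the consensus itself
is trimmed to columns covered by at least two reads.  Candidates whose
consensus is shorter than 10 bp, or whose stack holds strictly more than
50% mismatches, are discarded as likely mapping errors rather than allelic
heterogeneity.  Overlapping alleles with distinct breakpoints survive as
independent records; a shared-breakpoint stack that fails the divergence
filter is dropped whole, with no attempt to split sub-alleles.

## Partner-breakpoint resolution

Each supporting read's SA/XA entries imply a partner position: a tag
alignment covers the clipped piece of its read and soft-clips the anchored
piece, so the partner junction is the tag alignment's boundary adjacent to
its **larger clip**.  This rule is strand-safe (verified against simulated
inversions, whose supplementary pieces map to the opposite strand).  Tag
alignments without clips (typical full-length XA hits) carry no junction
information and are skipped; XA entries have no per-entry MAPQ (stored as
−1, never used in likelihoods).  When no tag yields a junction, discordant
mate positions serve as flagged, low-precision fallbacks that are clustered
but never SW-refined.

Implied positions are grouped on a 10 bp grid ("nearest tenth base pair",
read as half-up rounding to multiples of 10 — a 0.1 bp grid is meaningless
for integer coordinates); the best-supported cluster wins, ties to the
smallest coordinate.  Within the winning cluster the reported position is
the *modal exact endpoint* (the position most reads agree on), not the grid
point: the grid exists to absorb small disagreements during clustering, and
the large-SV filter below counts reads at an exact base.

If the consensus is at least 10 bp it is locally aligned (Smith-Waterman,
via Biopython's `PairwiseAligner`) in both orientations against the
reference window ±200 bp around the winning cluster.  Scoring is +2/−2 with
affine gaps −3/−1.  An alignment is accepted when it covers ≥90% of the
consensus, matches ≥80% of the consensus bases, **and** scores at least
`match·L·(2·identity_min − 1)` — the score of an ungapped full-length
alignment at the minimum identity.  The score floor matters: gap-stitched
chance chains in a 400 bp window occasionally reach the two count
thresholds (≈5% of random 30-mers) but never the score floor (0/1000 in the
package's own calibration test), while true junction sequences with ≤2
errors pass comfortably.  The junction-proximal end of the accepted
alignment is the refined partner position: alignment start for a forward
match of a right-side clip, alignment end for a left-side clip, flipped for
reverse-complement (inversion) matches.  The refined position may sit a few
bases from the modal SA endpoint — junction microhomology shifts the two
estimates differently — which is why distal support is counted at the modal
endpoint rather than demanding agreement with the refined base.

Large events get extra scrutiny: inter-chromosomal calls and
intra-chromosomal spans above 1 Mb are kept only when at least two reads
share the exact distal endpoint, and any candidate whose split reads map to
more than three chromosomes (SA entries counted, XA not) is discarded as
repeat-induced mapping noise.

## Genotyping

Reads covering a breakpoint are classified once each (strongest basis
wins): clipped exactly at a breakpoint, carrying an internal indel CIGAR op
≥10 bp over the breakpoint, discordant (|TLEN| > μ+3σ or inter-chromosomal
mate), or same-strand mate pair (the inversion signature) — all
alternative; clean spanning reads are reference.  Insert μ/σ are estimated
per run from the first 100,000 proper pairs with median/MAD (MAD scaled by
1.4826).

The likelihood is the standard bi-allelic per-read mixture used by
short-read SNP genotypers, with mapping quality in place of base quality:
with per-read error `e = min(10^(−MAPQ/10), 0.5)`, a genotype with `g`
alternative copies explains an alt observation with probability
`(g/2)(1−e) + (1−g/2)e`, and symmetrically for reference observations.
Likelihoods accumulate in log10 space; GLs are normalized to max 0; GT is
the flat-prior argmax; GQ is the phred of the posterior error.  Capping `e`
at 0.5 makes MAPQ-0 reads exactly uninformative (adding them provably never
changes the GLs).  Ploidy is fixed at 2 even for pooled inputs; pooled
analyses should read allele balance from the per-sample `SP:DP` FORMAT
fields rather than GT.

A known, deliberate behavior: junction reads that the aligner forced
through the breakpoint as full matches count as high-confidence reference
evidence, so homozygous events (especially duplications, whose reference
copy also contributes spanning reads) are frequently genotyped
heterozygous.  This mirrors what MAPQ-based SV genotypers do on real data
and is visible in the package's own simulations.

During joint calling a site is kept only if at least one individual has ≥3
alternative reads, which suppresses clip start/stop positions randomly
shared across individuals.

## Association test

With target and background cohorts, each site's called diploid genotypes
contribute allele counts (0/1/2 per sample; `./.` contributes nothing), and

    D = −2·[ ℓ(n_c, k_c, af_c) − ℓ(n_t, k_t, af_t) − ℓ(n_b, k_b, af_b) ]

where ℓ is the binomial **log-kernel** `n·ln p + (k−n)·ln(1−p)` with
0·ln 0 ≡ 0.  The kernels omit the combinatorial coefficients deliberately:
with coefficients the pooled-numerator form can go negative, while the
kernel form is algebraically the standard two-sample binomial LRT, so D ≥ 0
always and D is asymptotically χ²(1) under the null; p-values come from the
upper χ²(1) tail.  Sites where either cohort has no called alleles emit no
LRT rather than a NaN.

Because allele counts are discrete the null p-value distribution is not
literally U(0,1) — it carries an atom at p = 1 whenever the cohorts tie
(mass ≈0.19 for 8-vs-8 diploid cohorts), so a Kolmogorov–Smirnov test
against a continuous uniform rejects for *any* exact count statistic.  The
meaningful calibration property, asserted in the test suite, is that
rejection rates at nominal levels 0.01–0.2 match those levels to within
±0.05 under random splits of a single population.

The LRT is a first-pass tool for Mendelian-style contrasts; it does not
model population stratification, relatedness or quantitative traits, and
downstream tools should be used for those designs.

## SV-type classification

Classification is post hoc and never alters breakpoints, genotypes or the
LRT.  Fourteen depth-normalized attributes are computed over the combined
pileup at the call position — left/right clip fractions, SA and XA carrier
fractions, long/short discordant inserts, same-strand and everted pairs,
unmapped and other-chromosome mates, internal indels ≥10 bp, supplementary
records, MAPQ < 20, and duplicate-flagged reads — each a read count divided
by the pileup depth, emitted verbatim as the AT INFO field.  The attribute
identities and order are fixed in `classify.ATTRIBUTE_NAMES`; several carry
little signal on clean data (XA carriers, unmapped mates) but are retained
so user-supplied training sets can exploit them.  A 200-tree random forest
(scikit-learn, seed required, deterministic) is trained on labelled rows —
tab-delimited, 14 attribute columns plus a label column, with arbitrary
user-defined labels accepted — and reports stratified k-fold (default 5)
mean accuracy before refitting on all rows.  Predictions write the argmax
class to WC and the class probabilities (DEL, DUP, INS, INV order) to WP.

## Synthetic data generator

The generator defines the package's study conditions: 4 contigs × 5 Mb of
i.i.d. uniform ACGT sequence; 100 SVs per class (deletion, tandem
duplication, inter-chromosomal copy insertion, inversion) with log-uniform
sizes on [50 bp, 1 Mb], placed ≥1 kb apart with 2 kb contig-end margins —
when the genome fills, the size cap for further draws halves until a
placement fits, so the largest size stratum is thinner on small genomes
than the nominal law; 50x total coverage per diploid sample; 100 bp reads;
inserts Normal(400, 50); het/hom zygosity at 50/50 per sample, hets on a
random haplotype.  Insertion donors live on a different contig whenever
more than one exists; donor spans are reserved like any other SV interval.
All randomness flows from one mandatory seed through `SeedSequence`
children, and every output is reproducible byte-for-byte.

Evidence is synthesized at the *alignment level*: per-haplotype segment
maps translate fragment coordinates back to the reference, so junction
reads become soft-clipped records with SA tags pointing at the partner
locus, strand-flipped inside inversions, mate-everted across tandem
duplication junctions and inter-chromosomal for copy insertions, while pair
geometry (TLEN, orientation, proper-pair flags) emerges from the placements
themselves.  The emulated aligner is score-maximizing in the BWA-MEM mold:

* alignments extend base-by-base through chance junction microhomology, so
  reported clip boundaries can sit a few bases off the molecular junction,
  identically for every read over that junction;
* deletions small enough that the through-gap score beats the clipped score
  (overhang > deletion size + 1 under unit-match/affine-gap scoring) are
  absorbed as internal `D` CIGAR ops instead of clips;
* split pieces shorter than 20 bp (a seed length) get no SA entry;
* a `clip_fraction` (default 0.9) of junction reads is clipped cleanly; the
  rest are forced through as full matches;
* reads inside duplicated sample content (tandem-duplication spans,
  insertion donor copies) are reported at MAPQ 10 with an XA entry at the
  homologous locus, mirroring the depressed mapping confidence of CNV loci.

Library artifacts are modeled at literature-typical rates: substitution
errors at 10⁻³/bp, PCR duplicates at 3% (emitted duplicate-flagged),
chimeric ligation fragments at 1% (a mate drawn from an unrelated locus,
three quarters inter-chromosomal on a four-contig genome), and spurious
clipped tails on 2×10⁻⁴ of reads; 1% of reads get a background MAPQ below
20.  Reads are written as SAM text and sorted/indexed through samtools via
pysam.  An optional FASTQ emitter provides raw pairs for users who want a
true aligner round trip.

What the emulation does **not** model — and what passing benchmarks
therefore do not demonstrate about real data: reference repeats and
segmental duplications (the dominant cause of real-world false positives
and misses), mobile-element insertions, reference errors, base-quality
profiles, GC coverage bias, and genuine mapping ambiguity.  On this clean
substrate detection saturates: the measured overall sensitivity at 50x is
~1.0 and the FDR ~0, which should be read as "the caller loses essentially
nothing under ideal mapping", not as a real-data estimate.

## Benchmarking

Truth intervals are ±25 bp around every simulated breakpoint (insertion
truth includes the acceptor point and both donor-span edges — the three
reference coordinates where alignment collinearity breaks).  A call record
is a true positive only when both of its breakpoints (POS and the BE
partner) fall inside slop-extended truth intervals of the same truth SV.
Matching is greedy by call support with deterministic tie-breaks; one truth
SV can be recalled by at most one record, and because the caller emits the
5' and 3' breakpoints as independent records, the second record of a fully
recovered SV is a duplicate — neither TP nor FP.  Unmatched records count
as false positives individually.  Sensitivity = TP/(TP+FN) over truth SVs;
FDR = FP/(TP+FP); both are reported overall and per class × size bin
(left-closed bins 50 bp–1 kb, 1–10 kb, 10–100 kb, 100 kb–1 Mb).  FP rows
are stratified by the call's own classification and span, so per-stratum FP
columns are indicative while the overall row is exact.  The breakpoint
accuracy curve repeats the match at slops 1–500 bp against raw breakpoints
with no truth padding.

## Validation protocol and problem sizes

`clipsv.validation.run_validation` (wrapped by `scripts/acceptance.py`)
runs the default-scale study — 20 Mb genome, 400 SVs, 50x, one diploid
sample — and reports overall sensitivity and FDR at 25 bp truth intervals +
50 bp slop, deletion sensitivity at 1 bp slop, and the classifier's 5-fold
CV accuracy on attribute vectors at the true breakpoints.  The full
protocol runs in roughly 3–5 minutes on one CPU; the test suite reuses one
such run and otherwise works on 0.3–1.6 Mb genomes so the whole suite stays
within a few minutes.

## Numerical and interface choices

* Consensus ties break lexicographically; candidate and call ordering is a
  stable (chrom, pos, side) sort; the pipeline is single-threaded and a
  `threads` option is accepted for CLI compatibility only, so output bytes
  are invariant to it.
* Per-read likelihood terms are floored at 10⁻³⁰⁰ before taking logs; D is
  clipped at 0 against rounding noise.
* SW windows truncate at contig edges; empty windows skip refinement.
* Each breakpoint is emitted as its own VCF record carrying a `BE`
  (partner) pointer; a merged two-breakpoint representation would be a
  plausible alternative, but independent records keep the emission model
  simple and symmetric.
* Sample identity comes from read-group SM tags with the file basename as
  fallback; BAMs sharing an SM are one sample in the joint pileup.
* VCF floats use minimal exact decimal representation so a write/read
  round trip reproduces every numeric field bit-for-bit.

## Known limitations

Beyond the simulator's realism limits above: no CRAM or long-read support;
no multi-allelic genotyping; no breakpoint assembly; complex multi-break
events are reported as independent records rather than resolved; the
association test is unadjusted for structure/kinship; and the 14-attribute
vector is this package's own definition, so AT fields and trained models
are not interchangeable with other tools' classifiers.
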