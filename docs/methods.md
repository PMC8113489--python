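# Methods

## Problem

When a diploid genome is assembled into a single haploid representation,
both haplotypes of a divergent locus can survive as separate sequences.
The locus then *looks* duplicated in the assembly — and in any gene set
annotated from it — although the genome carries a single copy per haplotype.
These haplotype-induced duplication artifacts inflate assembly size and
BUSCO duplication rates, and they can masquerade as gene-family expansion.

`haplodepth` implements the depth-based diagnostics that separate this
failure mode from genuine duplication, together with a diploid genome
simulator that reproduces the statistical structure the diagnostics rely
on, so every statistic can be validated end-to-end against known truth.

## The duplication-artifact test

Reads from an individual are mapped to the assembly under evaluation.
For each conserved marker gene (a BUSCO-style gene with a copy-number
status label obtained elsewhere), the mean mapped read depth is computed
over the gene's full genomic range, every base counted, zero-depth bases
included. The two hypotheses make opposite predictions on a *collapsed*
(one-copy-per-locus) assembly:

* genuinely duplicated but erroneously collapsed genes attract the reads of
  both copies — twice the depth of single-copy genes;
* haplotype-artifact "duplications" are ordinary single-copy loci — no depth
  difference at all.

The duplicated and single-copy depth samples are compared with a one-sided
two-sample Kolmogorov–Smirnov test. With the duplicated class as the
putatively greater sample (sizes n1, n2):

    D+ = sup_x [ F_single(x) − F_duplicated(x) ]
    p  = exp( −2 D+² n1 n2 / (n1 + n2) ),  clamped to (0, 1]

This is the asymptotic form R's `ks.test` applies to one-sided two-sample
alternatives. Exact small-sample p-values are not implemented; a seeded
permutation p-value (`ks_permutation_pvalue`) is available where the
asymptotic approximation is a concern. At the class sizes used here
(tens of genes per class) the asymptotic test is mildly conservative: its
measured Type-I error on the simulator is ≈4.5% at α = 0.05.

As a positive control for detecting two-fold copy-number shifts, the same
machinery compares autosomal against X-linked genes: in a male sample the
hemizygous X runs at half the autosomal depth (reject), in a female sample
the depths match (no rejection).

## Sex-scaffold classification

Male and female read sets are mapped to the same assembly; depth is
summarised in fixed windows (default 100 kb) with the trailing partial
window dropped and, by default, the first and last full windows removed —
depth tapers at scaffold ends because fragments cannot overhang them.
Each sample is normalized (default: by the genome-wide median of its window
means, which is an autosomal depth as long as X windows are a minority;
alternatively by genome-wide mean depth, mimicking equal-input subsampling)
and the per-scaffold ratio R = male/female normalized mean depth is formed.
R ≈ 0.5 marks X-linked scaffolds, R ≈ 1 autosomes. Default call bands are
[0.35, 0.65] and [0.8, 1.2] (configurable; only "~0.5" is dictated by the
biology). Scaffolds with fewer than three full windows are never called.

## B-allele frequency and phase concordance

Per-site strand-resolved reference/alternate depths (DP4 semantics) are
tallied from the alignments; the alternate allele is the most frequent
non-reference base. A site is called a SNV when total DP4 depth ≥ 10 and
alternate fraction ≥ 0.2 — thresholds chosen so that, at 30x with 1%
sequencing error, false calls stay well under 1% of the truth count on the
simulator (measured: 0.34% with error-free reads at the default placer
settings, and errors at 1% add binomially negligible alt columns).
BAF = (alt_fwd + alt_rev) / DP4 total; heterozygous diploid sites sit near
0.5. Phase concordance reports, per scaffold, SNV density, the fraction of
SNVs inside phase blocks, runs of ≥5 consecutive outside-block SNVs
spanning ≥10 kb (heterozygous-but-unphased intervals), and a
low-heterozygosity flag below 0.1 SNV/kb (qualitative contrast only; no
published threshold exists).

## Transcript locus clustering

Loci are connected components of the graph joining same-scaffold,
same-strand transcripts sharing ≥1 bp of exonic overlap (threshold
configurable). Exon–intron structure matters: a transcript inside another's
intron shares no exonic sequence and is not joined. Single-exon transcripts
with unknown strand are excluded and reported separately. Opposite-strand
exonic overlaps between a reference and query set are flagged as anti-sense
artifact candidates and never counted as shared loci. Sampling one uniform
random isoform per locus (seeded) removes the isoform-inflation bias in
conserved-gene duplication estimates. Intron-chain containment beyond exon
overlap is deliberately not used as a join criterion.

## The simulator

The generator emulates, with complete truth tables:

* an ancestor sequence at configurable GC (default 32.21%);
* haplotype 2 diverging by heterozygous SNVs (default 4 per kb, matching
  sub-0.4% divergence dominated by SNVs) and short indels (default 0.4 per
  10 kb, lengths uniform on 1–10 bp), placed outside one contiguous
  homozygous block per scaffold (default 30% of its length — the inbreeding
  signature of long low-heterozygosity stretches);
* phase blocks as the central 80% of each heterozygous interval, leaving
  heterozygous-but-unphased margins;
* a collapsed rendering (haplotype 1) and an "artifact" rendering that
  appends the haplotype-2 copy of selected marker loci with a fixed 1 kb
  flank as extra scaffolds — the megabubbles-scaffolding failure mode (the
  junction structure of real scaffolding events is not modelled);
* genuine tandem duplications present in both haplotypes of the genome but
  kept at single copy in the collapsed rendering (the erroneous collapse
  the depth test is designed to expose);
* sexed 150-bp paired-end read sets (insert 350 ± 50 bp, uniform fragment
  start, per-base substitution errors, constant Q30 qualities — the
  analysis never consumes base qualities). Males carry one (haplotype-1)
  copy of each X scaffold, females two copies of everything.

`coverage` means expected depth on the collapsed assembly where the genome
is diploid; each haplotype copy is sampled at coverage/2, so pair count =
round(coverage × represented length / (4 × read length)) and a hemizygous
male X lands at half the autosomal depth.

What the simulator does **not** model: GC-dependent coverage bias, indel
sequencing errors, quality-score error profiles, structural variants beyond
the specified duplications, recombination, population samples, repeats
(sequences are i.i.d., so the genome is nearly repeat-free and the
repeat-mask filter is exercised with synthetic masks). Passing tests
therefore demonstrate correctness of the statistical machinery under the
model's assumptions, not robustness to every artifact of real libraries.

## Read placement

The internal placer is an exact-seed matcher, not a general aligner: a
sorted 2-bit 31-mer index of the assembly, seeds at both read ends and the
middle, ungapped full-length mismatch scoring of the candidate placements,
best score wins. Unique best placements get MAPQ 60; score ties are broken
uniformly at random (seeded) and marked MAPQ 0 — the conventional ambiguity
marker, which is exactly what the depth diagnostics filter on. The
mismatch budget is max(ceil(3·error_rate·L), ceil(0.03·L)): large enough to
retain reads from a diverged haplotype even in error-free runs, small
enough that reads overhanging an indel by more than a few bases go unplaced
instead of depositing false mismatch columns. Reads spanning indels between
haplotypes may be lost (ungapped scoring); this costs a few percent of
haplotype-2 reads near indels and is the main source of the ≈0.49 rather
than exactly 0.50 mean BAF on error-free simulations. Repeat-mask
filtering removes alignments *fully contained* in mask intervals
(containment, not overlap — the strictest reading); depth is computed after
all filters.

## Problem sizes

Fixed-seed validation runs use the full study-scale design: five 1 Mb
autosomes (plus two 1 Mb X scaffolds where sex matters), 100 marker genes
of 2 kb, 30x coverage. Replicate studies — 200 null replicates for the
Type-I rate, 50 for power, 20 seeds for the sex analyses — keep every rate,
class size and coverage identical but shorten scaffolds (50–200 kb): the
null distribution of the gene-class KS statistic depends on class sizes,
not scaffold length, and depth ratios are scale-free, while per-scaffold
ratio noise at the 200 kb replicate scale remains within the ±0.05 call
tolerance. These are the package's chosen problem sizes for its own
validation suite.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally everywhere, converted at I/O
boundaries (BUSCO tables and GTF are 1-based inclusive; BED and BAM are
0-based). Ties in the alternate-allele choice break alphabetically.
Duplicated marker genes with several recorded placements are measured on
the placement present in the assembly under test. An empty gene class makes
the artifact test report `untestable` instead of a p-value; a zero female
scaffold mean yields ratio NaN and an `unclassified` call. Histogram bins
in the artifact report default to (median single-copy depth)/10, the
coverage-scaled width used for report comparability.

## Known limitations

* The placer requires uniform read length and substitution-only differences;
  real BAM input should come from a full aligner (BWA-MEM or minimap2) and
  is consumed via `load_alignments`.
* The asymptotic one-sided KS p-value is conservative for small classes;
  use the permutation option when class sizes drop below ~20.
* Phase blocks are consumed and emitted as BED only; assembler-specific
  phase-block index formats are out of scope.
* SNV recall degrades when heterozygosity and sequencing error stack up:
  at 1% SNV rate plus 1% error the combined mismatch load pushes ~8% of
  alternate-allele reads over the placer budget (recall ≈92%, vs ≈97–99%
  on error-free reads). A gapped aligner upstream avoids this in real-data
  mode.
* X-linked ratio estimates carry a small (+2–3%) bias relative to 0.5
  because hemizygous X reads are all haplotype-1 and suffer no
  divergence-related placement loss, unlike diploid autosomes; this is a
  property of mapping, visible in real data too, and comfortably inside the
  default X band.
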