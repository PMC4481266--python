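# Methods

This note documents the models and decision rules `txrefine` implements,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical/design choices made where the procedure was
genuinely open.

## Coordinate model

All internal coordinates are 0-based half-open.  GTF is converted at the
boundary (1-based inclusive), VCF positions stay 1-based inside
`VariantRecord`.  An intron is identified by (chrom, start of first
intronic base, end exclusive, strand); exact equality of that tuple is the
unit of intron concordance.  Transcript strand `.` is permitted throughout
because strand-selection failure in library preparation is common; ORF
scans therefore cover both strands by default.

## Read processing

* End trimming removes maximal terminal runs of positions that are `N` or
  carry the quality *character* `B` (the Illumina-1.5 read-segment marker).
  The comparison is by character, not numeric score — that is the
  convention the B-tail encodes.  Trimming is idempotent.
* Adapter trimming removes the longest read suffix exactly matching a
  prefix of the adapter, with a configurable minimum overlap (default 5).
  Exact matching is the simplest well-defined rule; error-tolerant adapter
  matching is out of scope.
* Alignment filtering drops records with more than 3 mismatches and pairs
  that are not (same chromosome, opposite strands, 5'-to-5' span within
  [1, 500000] bp).  The insert window is configuration: callers tracking a
  real library should set it from the fragment-size distribution.
* Long reads of >= 50 nt become 2x25 bp end-segment pairs; a pair is kept
  when both segments have mean phred >= 28 (boundary inclusive).  A
  per-base-minimum mode is available (`quality_mode="min"`) because the
  historical description of the quality cut is ambiguous; mean is the
  default reading.

## Fragment linking and merging

Segments are placed exhaustively (both orientations, <= 1 mismatch) in the
spliced transcript sequences.  More than 3 placements discards the segment
entirely — suppression semantics, the conservative reading of an "up to 3
alignments" rule; report-best-3 would admit ambiguous links.

A link candidate requires: the two segments of one read in two different
transcripts, equal placement orientation, compatible genomic strands, the
5' segment in the transcript upstream in the direction of transcription
(roles swap when the read is reverse-complemented), non-overlapping spans,
and a genomic gap of at most 200,000 bp measured between the closest span
ends (span-gap, not midpoint distance; switchable).

Refinement split-aligns the full read across the junction by brute force
over split positions — prefix against the 3' end of the upstream spliced
sequence, suffix against the 5' start of the downstream one, minimal total
mismatches (cap 5) — rather than running a general spliced aligner: at desk
scale exactness and testability win.  The implied intron (the genomic gap
between the two transcripts' facing exon boundaries) is accepted only when
an annotated intron agrees within 10 bp at the donor **and** the acceptor;
the single-sided reading of "within 10 bp of an intron" is looser and is
available by configuration.  Non-canonical-junction merging requires the
junction's donor and acceptor to coincide exactly with terminal exon
boundaries of two distinct transcripts; ambiguous attachments are logged
and skipped.  All accepted connections (read links and junction links) are
applied as connected components; merged exon sets are unions with
overlapping/abutting exons joined, so no exonic base is lost.  The merge
report TSV replaces the original protocol's manual review step.

## Evidence filtering

The aligner is an exact Smith–Waterman with affine gaps (no seeding or
heuristics; an optional k-mer prefilter exists but is off by default).
Default scheme: match +1, mismatch −2, gap open −5, gap extend −2.  `N`
never counts as a match.  The row recurrence vectorizes the in-row gap
state as a prefix scan, which is valid whenever reopening a gap immediately
after closing one is not cheaper than extending (gap open <= 0); the test
suite checks it against an independent quadratic three-matrix DP.

Bit conversion is `bits = (λS − ln K) / ln 2`, with λ = 1.28 and K = 0.46
as documented approximations for the +1/−2 scheme; both are configuration,
and the filter's contract is the conversion formula plus the threshold, not
any historical aligner's constants.  The threshold is >= 400 bits,
inclusive (a hit at exactly 400 retains the transcript).  Transcripts with
more than two exons are never filtered.

## Annotation concordance

Gene loci are single-linkage connected components under ">= 1 bp exonic
overlap on the same chromosome with compatible strands" (`.` bridges both).
A `gene_id`-trusting mode exists because locus counts can also be computed
from assembler-assigned gene ids; positional clustering is the default.
Gene-span overlap is deliberately strand-agnostic (the rule compares
chr:start–stop spans only) while intron matching is strand-aware — the two
rules are quoted conventions, not an inconsistency.  Unplaced-contig
transcripts are recognized by a configurable chromosome-name substring
(default `"Un"`).

## Variant analysis

Hard filters use strict inequalities at the published thresholds; a record
fails when any applicable rule triggers and carries every triggered rule
name.  A missing INFO metric skips that rule: callers omit rank-sum metrics
at homozygous sites, and failing such records would discard exactly the
candidate reference errors the analysis exists to find.  The
HaplotypeScore rule applies only in genomic mode.  Records whose ref and
alt are both multi-base ("mixed") run under the indel rules.

Genotype categories: identical non-reference alleles → `homozygous_alt`;
one reference plus one alternate → `mixed_allele` (pooled samples cannot
distinguish heterozygosity from two individuals); two different
non-reference alleles → `other`; no call → `missing`.  GT 0/0, which
genomic calling at RNA-derived positions can produce, is reported as
`homozygous_ref` and is treated as no support downstream.

Normalization trims shared trailing then leading bases and left-aligns
indels against the genome (the standard canonical form), so the same
homopolymer deletion reported at the first or the last base of a run
compares equal.  Known-variant matching and cross-dataset support both
operate on normalized (chrom, pos, ref, alt) allele keys; a position-only
matching mode is available.  Multi-allelic sites are one record ("variant
position"); per-allele analyses iterate the alternates.

## ORF consequence and reference-error calls

A transcript sequence is the 5'→3' concatenation of exon sequences
(reverse-complemented for `-` strand) with a bijective genomic↔transcript
coordinate map.  One variant is applied at a time; variants partially
overlapping an exon boundary or fully intronic are skipped with reason
codes.  An ORF is ATG through stop codon inclusive, scanned over 3 frames
of both strands; ORFs truncated by the sequence end do not count.  Ties
break to the forward strand, then the smaller start offset.  A
`stop_to_stop` mode exists for sensitivity analysis; because effects are
classified from length *differences*, the ATG-to-stop choice does not
change effect labels.

An extending variant is classed by the reference individual's genomic
evidence: `homozygous` (candidate reference error), `heterozygous`, or
`unsupported`; matching goes through the same normalization, so RNA-side
and DNA-side representations of one homopolymer indel agree.  Mechanism
flags: *homopolymer slip* — the inserted/deleted bases are identical to
each other and to the genomic base on either flank of the normalized event
(both flanks are checked because the direction of slippage is unknowable);
*intron mimic* — some annotated intron has exactly the deletion's length
and a start within 10 bp of the deletion start.  Mechanism tallies in the
run report cover extending indels with genomic support (homozygous or
heterozygous), matching how such diagnostics are quoted.

## Synthetic data

The generator works backwards from biology: each "reference error" is an
edit planted in the *reference* copy of a gene whose true transcript
carries a long clean ORF.  A deletion-type error gives the reference one
extra homopolymer base (run of 5 C vs the true 4), an insertion-type error
one base too few, a SNP-type error turns a TGG codon into a premature TGA
stop, and the intron-mimic error inserts a 30 bp stop-bearing segment that
the annotated gene structure splices out as an intron.  Downstream of each
planted frameshift the coding sequence carries a guard
(`CTA ATA ACT AAC` — stop-free in frame, stop-bearing in both shifted
frames) so the reference copy's ORF terminates promptly; a generation-time
self-check reruns the package's own ORF comparison and redraws the gene if
the planted edit is not extending.  RNA, genomic, comparison and
known-variant VCFs are all derived from the same truth-vs-reference
difference, which guarantees internal consistency; homopolymer indels are
expressed at right-shifted in-run offsets in half the genomic/comparison
records to exercise normalization.

Default conditions (fixed once): 2 chromosomes (`chr1`, `chrUn`) × 100 kb;
30 genes (2–7 exons, exons 120–400 bp, introns 70–400 bp, 10%
non-canonical splice sites); 8 fragmented transcripts with 2 linking long
reads each (substitution rate 0.005, at most one error per 25 bp end so a
linking read remains placeable under the 1-mismatch rule) plus contained
and low-quality decoy reads; 10 planted reference errors (3 SNP, 3
insertion, 4 deletion, one deletion being the 30 bp intron mimic); 3
heterozygous and 3 unsupported ORF-extending decoys; 12 neutral 3'-UTR
polymorphisms; 8 records each violating exactly one hard-filter rule
(passing metrics drawn QD~U(5,30), MQ~U(50,60), FS~U(0,10),
rank-sums~U(−2,2)); 5 comparison datasets sharing each variant with
probability 0.6; known-set membership 0.3.  Fragmentation hosts and the
intron-mimic host are drawn from annotated genes, because the link-
acceptance rule and the mimic diagnostic are both defined relative to
annotated introns.  Everything is driven by one `numpy` generator seeded
from the config, so a fixed seed yields byte-identical files.

What the generator does **not** emulate: realistic coverage and error
models, base-quality structure beyond pass/fail placement, assembler
behaviour (fragmentation is planted, not emergent), population structure
in the comparison sets, and multi-variant haplotypes (one variant is
applied at a time).  Passing tests therefore demonstrate that the decision
logic is implemented exactly and recovers planted signal under clean
conditions — not that the thresholds themselves are optimal for any real
dataset.

## Problem sizes and numerics

The test suite and the acceptance script run the full pipeline at the toy
scale above (a complete simulate + run-all pass takes a few seconds).
Oracle checks use 200 random pairs (length <= 60) for the alignment DP, 500
sequences up to 3 kb for the ORF scan, 20 trials of 500 random intervals
for the overlap/concordance brute force, and 200 random homopolymer
representations for normalization.  Scores are integer arithmetic
throughout the aligner; bit scores are the only floating-point quantity
and are compared with >=, never equality, at the filter boundary.

## Known limitations

* Merging is intra-chromosomal and uses one read's two end segments only.
* The evidence filter is O(|query| × |subject|) per pair — exact by design,
  not suitable for genome-scale databases.
* E-values are not computed (the filter is a bit-score cutoff).
* Locus clustering with `.`-strand transcripts can bridge opposite-strand
  transcripts into one locus (a consequence of single linkage).
* `normalize_variant` fully normalizes bi-allelic records only;
  multi-allelic records are compared per normalized allele instead.
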