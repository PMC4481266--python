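"""Score transcripts against three annotation sources.

Transcripts cluster into gene loci by single-linkage exonic overlap; each
transcript's span is compared against annotated gene spans (>= 1 bp,
strand-agnostic) and each intron against annotated introns (exact chrom,
start, end and strand).  The tallies mirror the published Venn and
per-locus summaries.
"""

from txrefine.concordance import (
    cluster_loci,
    intron_concordance,
    overlap_gene_annotations,
    summarize_annotation,
)
from txrefine.simulate import SimulationConfig, simulate

dataset = simulate(SimulationConfig(seed=1))
transcripts = dataset.truth_transcripts  # the refined (merged) structures

loci = cluster_loci(transcripts)
categories = overlap_gene_annotations(transcripts, dataset.annotation_sets)
introns = [i for t in transcripts for i in t.introns()]
sources = intron_concordance(introns, dataset.annotation_sets)
summary = summarize_annotation(transcripts, loci, categories, list(zip(introns, sources)))

print("gene loci:", summary.n_loci)
print("loci with >=2-exon transcript:", summary.loci_min2_exons)
print("loci with >=3-exon transcript:", summary.loci_min3_exons)
print("transcript Venn regions:", summary.venn_transcripts)
print("intron Venn regions:", summary.venn_introns)
pct = 100 * (summary.n_transcripts - summary.venn_transcripts["none"]) / summary.n_transcripts
print(f"transcripts overlapping any annotated gene locus: {pct:.0f}%")

# Region labels: E = Ensembl only, R = RefSeq only, O = other-species RefSeq
# only, two/three-letter codes are the intersections, and 'none' counts
# transcripts at previously unannotated loci.
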