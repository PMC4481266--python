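"""Generate the synthetic study dataset and inspect its planted ground truth.

The generator emulates the shapes of a transcriptome-annotation study: a
small two-chromosome genome, 30 multi-exon genes, fragmented transcript
assemblies with linking long reads, three overlapping annotation sources,
and variant call sets in which reference-genome errors are planted by
construction.
"""

from txrefine.simulate import SimulationConfig, simulate

dataset = simulate(SimulationConfig(seed=1))

print("chromosomes:", {name: len(seq) for name, seq in dataset.genome.items()})
print("true transcripts:", len(dataset.truth_transcripts))
print("assembled transcripts (with fragments + noise):", len(dataset.assembled_transcripts))
print("long reads:", len(dataset.long_reads))
print("RNA variant records:", len(dataset.rna_records))
print("planted fragmentations:", len(dataset.truth.true_links))
n_errors = sum(1 for p in dataset.truth.planted if p.group == "planted_error")
print("planted reference errors:", n_errors)

# Writing the dataset produces plain-text files (FASTA/GTF/BED12/FASTQ/VCF)
# that the file-based pipeline entry point consumes:
#   dataset.write("scratch/demo_data")
#
# Expected output: 2 chromosomes of 100 kb, 30 true transcripts, 44 assembled
# models (8 genes split into 2 fragments each, plus 6 intergenic noise
# models), 8 fragmentations and 10 planted errors.
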