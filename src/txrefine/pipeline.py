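"""End-to-end orchestration: trimming/segmenting, link and junction merging,
evidence filtering, annotation concordance, variant hard-filtering, ORF
consequence analysis and reference-error calling, with deterministic reports.
"""

from __future__ import annotations

import glob
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import io as txio
from .concordance import (
    ConcordanceSummary,
    cluster_loci,
    intron_concordance,
    overlap_gene_annotations,
    summarize_annotation,
)
from .homology import DEFAULT_SCHEME, ScoringScheme, filter_low_evidence
from .linkmerge import (
    JunctionRecord,
    LinkRejection,
    MergeResult,
    align_segment,
    apply_merges,
    find_link_candidates,
    merge_by_noncanonical_junction,
    refine_link,
)
from .models import (
    AlignmentRecord,
    AnnotationSet,
    GenomeSequence,
    ReadRecord,
    TranscriptModel,
    VariantRecord,
)
from .orf import (
    OrfEffect,
    ReferenceErrorCall,
    VariantApplicationSkip,
    build_transcript_sequence,
    call_reference_errors,
    classify_orf_effect,
)
from .reads import filter_alignments, prepare_segment_pairs, trim_read_ends
from .variants import (
    DEFAULT_THRESHOLDS,
    HardFilterThresholds,
    SupportTable,
    apply_hard_filters,
    classify_genotype_position,
    match_known_variants,
    tabulate_dataset_support,
)

SUPPORT_CLASSES = ("homozygous", "heterozygous", "unsupported")
VARIANT_CLASSES = ("snp", "insertion", "deletion")


@dataclass
class PipelineParams:
    """All stage parameters with their published defaults."""

    max_mismatches: int = 3
    insert_min: int = 1
    insert_max: int = 500_000
    segment_min_length: int = 50
    segment_min_quality: float = 28.0
    quality_mode: str = "mean"
    segment_max_hits: int = 3
    segment_max_mismatches: int = 1
    link_max_gap: int = 200_000
    link_tolerance: int = 10
    link_max_total_mismatches: int = 5
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    threshold_bits: float = 400.0
    max_exons_filtered: int = 2
    thresholds: HardFilterThresholds = field(default_factory=HardFilterThresholds)
    mimic_tolerance: int = 10
    unplaced_pattern: str = "Un"
    locus_mode: str = "overlap"
    known_match_by: str = "position_allele"


@dataclass
class PipelineInputs:
    genome: GenomeSequence
    transcripts: List[TranscriptModel]
    annotation_sets: List[AnnotationSet]
    long_reads: List[ReadRecord] = field(default_factory=list)
    alignments: List[AlignmentRecord] = field(default_factory=list)
    junctions: List[JunctionRecord] = field(default_factory=list)
    rna_records: List[VariantRecord] = field(default_factory=list)
    genomic_records: List[VariantRecord] = field(default_factory=list)
    known_records: List[VariantRecord] = field(default_factory=list)
    comparison_records: List[List[VariantRecord]] = field(default_factory=list)
    evidence: Dict[str, str] = field(default_factory=dict)


@dataclass
class RunReport:
    """Paper-shaped summary of one pipeline run (JSON round-trippable)."""

    stage_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    concordance: ConcordanceSummary = field(default_factory=ConcordanceSummary)
    support_table: SupportTable = field(default_factory=lambda: SupportTable(0))
    support_table_with_genomic: SupportTable = field(default_factory=lambda: SupportTable(0))
    genotype_counts: Dict[str, int] = field(default_factory=dict)
    error_matrix: Dict[str, Dict[str, int]] = field(default_factory=dict)
    mechanism: Dict[str, int] = field(default_factory=dict)
    known_fraction: float = 0.0
    skipped: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> Dict:
        return {
            "stage_counts": {k: dict(sorted(v.items())) for k, v in sorted(self.stage_counts.items())},
            "concordance": self.concordance.to_dict(),
            "support_table": self.support_table.to_dict(),
            "support_table_with_genomic": self.support_table_with_genomic.to_dict(),
            "genotype_counts": dict(sorted(self.genotype_counts.items())),
            "error_matrix": {k: dict(v) for k, v in self.error_matrix.items()},
            "mechanism": dict(sorted(self.mechanism.items())),
            "known_fraction": self.known_fraction,
            "skipped": dict(sorted(self.skipped.items())),
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "RunReport":
        return cls(
            stage_counts={k: dict(v) for k, v in d["stage_counts"].items()},
            concordance=ConcordanceSummary.from_dict(d["concordance"]),
            support_table=SupportTable.from_dict(d["support_table"]),
            support_table_with_genomic=SupportTable.from_dict(d["support_table_with_genomic"]),
            genotype_counts=dict(d["genotype_counts"]),
            error_matrix={k: dict(v) for k, v in d["error_matrix"].items()},
            mechanism=dict(d["mechanism"]),
            known_fraction=d["known_fraction"],
            skipped=dict(d["skipped"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls.from_dict(json.loads(text))


@dataclass
class PipelineResult:
    report: RunReport
    final_transcripts: List[TranscriptModel]
    merged_provenance: Dict[str, List[str]]
    merges: List[MergeResult]
    link_rejections: List[LinkRejection]
    effects: List[OrfEffect]
    error_calls: List[ReferenceErrorCall]
    rna_passing: List[VariantRecord]
    rna_failing: List[Tuple[VariantRecord, List[str]]]
    genomic_passing: List[VariantRecord]
    excluded_transcripts: List[TranscriptModel]


def run_pipeline(inputs: PipelineInputs, params: Optional[PipelineParams] = None) -> PipelineResult:
    """Execute every stage in order on in-memory inputs."""
    params = params or PipelineParams()
    report = RunReport()
    skipped: Dict[str, int] = {}

    # --- stage: read processing -------------------------------------------
    trimmed = [trim_read_ends(r) for r in inputs.long_reads]
    trimmed = [r for r in trimmed if len(r) > 0]
    segment_pairs, seg_stats = prepare_segment_pairs(
        trimmed,
        min_length=params.segment_min_length,
        min_quality=params.segment_min_quality,
        quality_mode=params.quality_mode,
    )
    kept_alignments, aln_stats = filter_alignments(
        inputs.alignments,
        max_mismatches=params.max_mismatches,
        insert_min=params.insert_min,
        insert_max=params.insert_max,
    )
    report.stage_counts["read_processing"] = {
        "long_reads_in": len(inputs.long_reads),
        "segment_pairs": seg_stats.emitted,
        "segments_skipped_short": seg_stats.skipped_short,
        "segments_skipped_quality": seg_stats.skipped_quality,
        "alignments_in": len(inputs.alignments),
        "alignments_kept": aln_stats.kept,
        "alignments_dropped_mismatches": aln_stats.dropped_mismatches,
        "alignments_dropped_improper": aln_stats.dropped_improper_pair,
        "alignments_dropped_orphan": aln_stats.dropped_orphan,
    }

    # --- stage: link merging ----------------------------------------------
    transcripts = {t.transcript_id: t for t in inputs.transcripts}
    tseqs = {
        tid: build_transcript_sequence(t, inputs.genome) for tid, t in transcripts.items()
    }
    tseq_strings = {tid: ts.sequence for tid, ts in tseqs.items()}
    read_by_id = {r.read_id: r for r in inputs.long_reads}
    segment_alignments = {}
    for pair in segment_pairs:
        aln5 = align_segment(
            pair.segment5.sequence,
            pair.segment5.read_id,
            tseq_strings,
            max_hits=params.segment_max_hits,
            max_mismatches=params.segment_max_mismatches,
        )
        aln3 = align_segment(
            pair.segment3.sequence,
            pair.segment3.read_id,
            tseq_strings,
            max_hits=params.segment_max_hits,
            max_mismatches=params.segment_max_mismatches,
        )
        segment_alignments[pair.source_read_id] = (aln5, aln3)
    candidates = find_link_candidates(
        segment_alignments, transcripts, max_gap=params.link_max_gap
    )
    pooled_introns = sorted(
        {intron for ann in inputs.annotation_sets for intron in ann.introns}
    )
    merges: List[MergeResult] = []
    rejections: List[LinkRejection] = []
    for cand in candidates:
        outcome = refine_link(
            read_by_id[cand.read_id].sequence,
            inputs.genome,
            cand,
            tseqs,
            transcripts,
            pooled_introns,
            tolerance=params.link_tolerance,
            max_total_mismatches=params.link_max_total_mismatches,
        )
        if isinstance(outcome, MergeResult):
            merges.append(outcome)
        else:
            rejections.append(outcome)
            skipped[f"link_{outcome.reason}"] = skipped.get(f"link_{outcome.reason}", 0) + 1
    junction_merges, junction_log = merge_by_noncanonical_junction(
        inputs.transcripts, inputs.junctions
    )
    merged_transcripts, provenance = apply_merges(
        inputs.transcripts, merges + junction_merges
    )
    report.stage_counts["link_merge"] = {
        "transcripts_in": len(inputs.transcripts),
        "link_candidates": len(candidates),
        "links_accepted": len(merges),
        "links_rejected": len(rejections),
        "junction_merges": len(junction_merges),
        "junction_ambiguous": len(junction_log),
        "transcripts_out": len(merged_transcripts),
    }

    # --- stage: evidence filter --------------------------------------------
    merged_seqs = {
        t.transcript_id: build_transcript_sequence(t, inputs.genome).sequence
        for t in merged_transcripts
    }
    kept, excluded, hits = filter_low_evidence(
        merged_transcripts,
        merged_seqs,
        inputs.evidence,
        scheme=params.scheme,
        threshold_bits=params.threshold_bits,
        max_exons_filtered=params.max_exons_filtered,
    )
    report.stage_counts["evidence_filter"] = {
        "transcripts_in": len(merged_transcripts),
        "kept": len(kept),
        "excluded": len(excluded),
    }
    final_transcripts = sorted(kept, key=lambda t: (t.chrom, t.span_start, t.transcript_id))

    # --- stage: annotation comparison ---------------------------------------
    loci = cluster_loci(final_transcripts, by=params.locus_mode)
    categories = overlap_gene_annotations(final_transcripts, inputs.annotation_sets)
    all_introns = [i for t in final_transcripts for i in t.introns()]
    intron_sources = intron_concordance(all_introns, inputs.annotation_sets)
    summary = summarize_annotation(
        final_transcripts,
        loci,
        categories,
        list(zip(all_introns, intron_sources)),
        unplaced_pattern=params.unplaced_pattern,
    )
    report.concordance = summary

    # --- stage: variant filtering and classification -------------------------
    rna_passing, rna_failing = apply_hard_filters(
        inputs.rna_records, params.thresholds, use_haplotype_score=False
    )
    genomic_passing, genomic_failing = apply_hard_filters(
        inputs.genomic_records, params.thresholds, use_haplotype_score=True
    )
    genotype_counts: Dict[str, int] = {}
    for rec in rna_passing:
        cat = classify_genotype_position(rec)
        genotype_counts[cat] = genotype_counts.get(cat, 0) + 1
    known_fraction = 0.0
    if inputs.known_records:
        _, known_fraction = match_known_variants(
            rna_passing, inputs.known_records, inputs.genome, by=params.known_match_by
        )
    support = tabulate_dataset_support(
        rna_passing, inputs.comparison_records, inputs.genome
    )
    support_with_genomic = tabulate_dataset_support(
        rna_passing, inputs.comparison_records, inputs.genome, extra_set=genomic_passing
    )
    report.stage_counts["variants"] = {
        "rna_in": len(inputs.rna_records),
        "rna_passing": len(rna_passing),
        "rna_failing": len(rna_failing),
        "genomic_in": len(inputs.genomic_records),
        "genomic_passing": len(genomic_passing),
        "genomic_failing": len(genomic_failing),
    }
    report.genotype_counts = genotype_counts
    report.known_fraction = known_fraction
    report.support_table = support
    report.support_table_with_genomic = support_with_genomic

    # --- stage: ORF consequence and reference-error calling -------------------
    final_seqs = {
        t.transcript_id: build_transcript_sequence(t, inputs.genome)
        for t in final_transcripts
    }
    by_chrom: Dict[str, List[TranscriptModel]] = {}
    for t in final_transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    effects: List[OrfEffect] = []
    for rec in rna_passing:
        for t in by_chrom.get(rec.chrom, []):
            if not (t.span_start < rec.pos <= t.span_end):
                continue
            for alt_index in range(len(rec.alt_alleles)):
                try:
                    effects.append(
                        classify_orf_effect(
                            final_seqs[t.transcript_id],
                            rec,
                            genome=inputs.genome,
                            alt_index=alt_index,
                        )
                    )
                except VariantApplicationSkip as skip:
                    skipped[f"orf_{skip.reason}"] = skipped.get(f"orf_{skip.reason}", 0) + 1
    calls = call_reference_errors(
        effects,
        genomic_passing,
        genome=inputs.genome,
        annotation_introns=pooled_introns,
        tolerance=params.mimic_tolerance,
    )
    matrix = {sc: {vc: 0 for vc in VARIANT_CLASSES} for sc in SUPPORT_CLASSES}
    mechanism = {"homopolymer_slips": 0, "intron_mimics": 0, "supported_extending_indels": 0}
    for call in calls:
        if call.variant_class in matrix[call.support_class]:
            matrix[call.support_class][call.variant_class] += 1
        if call.support_class in ("homozygous", "heterozygous") and call.variant_class in (
            "insertion",
            "deletion",
        ):
            mechanism["supported_extending_indels"] += 1
            if call.homopolymer_slip:
                mechanism["homopolymer_slips"] += 1
            if call.intron_mimic:
                mechanism["intron_mimics"] += 1
    report.error_matrix = matrix
    report.mechanism = mechanism
    report.stage_counts["orf_consequence"] = {
        "effects": len(effects),
        "extending": sum(1 for e in effects if e.effect == "extending"),
        "shortening": sum(1 for e in effects if e.effect == "shortening"),
        "neutral": sum(1 for e in effects if e.effect == "neutral"),
        "error_calls": len(calls),
        "candidate_errors": sum(1 for c in calls if c.is_candidate_error),
    }
    report.skipped = skipped

    return PipelineResult(
        report=report,
        final_transcripts=final_transcripts,
        merged_provenance=provenance,
        merges=merges + junction_merges,
        link_rejections=rejections,
        effects=effects,
        error_calls=calls,
        rna_passing=rna_passing,
        rna_failing=rna_failing,
        genomic_passing=genomic_passing,
        excluded_transcripts=excluded,
    )


def inputs_from_dataset(dataset) -> PipelineInputs:
    """PipelineInputs from an in-memory synthetic dataset."""
    return PipelineInputs(
        genome=dataset.genome,
        transcripts=dataset.assembled_transcripts,
        annotation_sets=dataset.annotation_sets,
        long_reads=dataset.long_reads,
        alignments=dataset.alignments,
        junctions=dataset.junctions,
        rna_records=dataset.rna_records,
        genomic_records=dataset.genomic_records,
        known_records=dataset.known_records,
        comparison_records=dataset.comparison_records,
        evidence=dataset.evidence,
    )


# ---------------------------------------------------------------------------
# file-based orchestration


def load_inputs(data_dir: str) -> PipelineInputs:
    """Load a dataset directory written by the synthetic generator (or with
    the same file naming)."""

    def _read(name: str) -> str:
        with open(os.path.join(data_dir, name)) as fh:
            return fh.read()

    annotation_sets = []
    for path in sorted(glob.glob(os.path.join(data_dir, "annotation_*.bed"))):
        label = os.path.basename(path)[len("annotation_") : -len(".bed")]
        with open(path) as fh:
            annotation_sets.append(txio.parse_bed12(fh.read(), label))
    comparison = []
    for path in sorted(glob.glob(os.path.join(data_dir, "comparison_*.vcf"))):
        with open(path) as fh:
            comparison.append(txio.parse_vcf(fh.read()))

    def _optional(name: str, parser, default):
        path = os.path.join(data_dir, name)
        if not os.path.exists(path):
            return default
        with open(path) as fh:
            return parser(fh.read())

    return PipelineInputs(
        genome=txio.parse_fasta(_read("genome.fa")),
        transcripts=txio.parse_gtf(_read("assembled.gtf")),
        annotation_sets=annotation_sets,
        long_reads=_optional("long_reads.fastq", txio.parse_fastq, []),
        alignments=_optional("alignments.tsv", txio.parse_alignment_tsv, []),
        junctions=_optional("junctions.tsv", txio.parse_junction_tsv, []),
        rna_records=_optional("rna.vcf", txio.parse_vcf, []),
        genomic_records=_optional("genomic.vcf", txio.parse_vcf, []),
        known_records=_optional("known.vcf", txio.parse_vcf, []),
        comparison_records=comparison,
        evidence=_optional("evidence.fa", txio.parse_fasta, {}),
    )


def write_report(report: RunReport, out_dir: str) -> None:
    """Write the report as JSON plus the paper-shaped TSV tables."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        fh.write(report.to_json() + "\n")
    # Table 1 shape: support bins per variant class
    with open(os.path.join(out_dir, "support_table.tsv"), "w") as fh:
        for name, table in (
            ("comparison_only", report.support_table),
            ("including_genomic", report.support_table_with_genomic),
        ):
            ks = list(range(1, table.n_sets + 1))
            fh.write(f"#{name}\t" + "\t".join(str(k) for k in ks) + "\tnot_validated\n")
            for cls in VARIANT_CLASSES:
                bins = table.bins.get(cls, {})
                row = [str(bins.get(k, 0)) for k in ks] + [str(bins.get(0, 0))]
                fh.write(cls + "\t" + "\t".join(row) + "\n")
    # Table 2 shape: support class x variant class
    with open(os.path.join(out_dir, "error_matrix.tsv"), "w") as fh:
        fh.write("support_class\t" + "\t".join(VARIANT_CLASSES) + "\n")
        for sc in SUPPORT_CLASSES:
            row = report.error_matrix.get(sc, {})
            fh.write(sc + "\t" + "\t".join(str(row.get(vc, 0)) for vc in VARIANT_CLASSES) + "\n")
    with open(os.path.join(out_dir, "venn.tsv"), "w") as fh:
        fh.write("region\ttranscripts\tintrons\n")
        for region in ("E", "R", "O", "ER", "EO", "RO", "ERO", "none"):
            fh.write(
                f"{region}\t{report.concordance.venn_transcripts.get(region, 0)}"
                f"\t{report.concordance.venn_introns.get(region, 0)}\n"
            )


def write_outputs(result: PipelineResult, out_dir: str) -> None:
    """Write every artifact of a run: final GTF, reports, effect/call tables."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "final.gtf"), "w") as fh:
        txio.write_gtf(result.final_transcripts, fh)
    with open(os.path.join(out_dir, "merge_report.tsv"), "w") as fh:
        fh.write("transcript_a\ttranscript_b\tintron\tmechanism\treads\n")
        for m in sorted(result.merges, key=lambda m: (m.transcript_a_id, m.transcript_b_id)):
            intron = f"{m.linking_intron.chrom}:{m.linking_intron.start}-{m.linking_intron.end}"
            fh.write(
                f"{m.transcript_a_id}\t{m.transcript_b_id}\t{intron}\t{m.mechanism}\t"
                + ",".join(m.supporting_read_ids)
                + "\n"
            )
    with open(os.path.join(out_dir, "effects.tsv"), "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tvariant_id\ttranscript\tclass\torf_ref\torf_alt\teffect\n"
        )
        for e in sorted(result.effects, key=lambda e: (e.variant_key, e.transcript_id)):
            c, p, r, a = e.variant_key
            fh.write(
                f"{c}\t{p}\t{r}\t{a}\t{e.variant_id}\t{e.transcript_id}\t{e.variant_class}\t"
                f"{e.longest_orf_ref}\t{e.longest_orf_alt}\t{e.effect}\n"
            )
    with open(os.path.join(out_dir, "error_calls.tsv"), "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tvariant_id\ttranscript\tclass\tsupport\t"
            "homopolymer_slip\tintron_mimic\n"
        )
        for call in sorted(result.error_calls, key=lambda c: c.variant_key):
            c, p, r, a = call.variant_key
            fh.write(
                f"{c}\t{p}\t{r}\t{a}\t{call.variant_id}\t{call.transcript_id}\t"
                f"{call.variant_class}\t{call.support_class}\t"
                f"{int(call.homopolymer_slip)}\t{int(call.intron_mimic)}\n"
            )
    failing_tags = {}
    records = [rec for rec, _ in result.rna_failing]
    for i, (_rec, reasons) in enumerate(result.rna_failing):
        failing_tags[i] = ";".join(reasons)
    with open(os.path.join(out_dir, "rna_failing.vcf"), "w") as fh:
        txio.write_vcf(records, fh, filter_tags=failing_tags)
    with open(os.path.join(out_dir, "rna_passing.vcf"), "w") as fh:
        txio.write_vcf(result.rna_passing, fh)
    write_report(result.report, out_dir)


def run_from_dir(
    data_dir: str, out_dir: str, params: Optional[PipelineParams] = None
) -> PipelineResult:
    """Load a dataset directory, run the pipeline, and write all outputs."""
    inputs = load_inputs(data_dir)
    result = run_pipeline(inputs, params)
    write_outputs(result, out_dir)
    return result
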