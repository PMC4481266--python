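"""Readers and writers for the text formats the pipeline touches.

GTF exon features are read and written 1-based inclusive and converted to the
internal 0-based half-open convention; BED12 is already half-open; VCF keeps
its 1-based positions.  FASTA/FASTQ go through Bio.SeqIO.
"""

from __future__ import annotations

import io as _io
import re
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple, Union

from Bio import SeqIO

from .models import (
    AnnotationSet,
    ExonInterval,
    GenomeSequence,
    IntronKey,
    ReadRecord,
    TranscriptModel,
    ValidationError,
    VariantRecord,
    sorted_transcripts,
    validate_genome,
)

Stream = Union[str, TextIO]


class ParseError(ValueError):
    """A malformed line in an input file (carries the line number)."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def _as_handle(stream: Stream) -> TextIO:
    if isinstance(stream, str):
        return _io.StringIO(stream)
    return stream


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gtf(stream: Stream) -> List[TranscriptModel]:
    """Parse GTF exon features into TranscriptModels (grouped by transcript_id)."""
    handle = _as_handle(stream)
    exons: Dict[str, List[ExonInterval]] = {}
    strands: Dict[str, str] = {}
    gene_ids: Dict[str, Optional[str]] = {}
    attrs: Dict[str, Dict[str, str]] = {}
    order: List[str] = []
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"expected 9 tab-separated fields, got {len(fields)}", lineno)
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
        if feature != "exon":
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno)
        attr = dict(_ATTR_RE.findall(attr_s))
        tid = attr.get("transcript_id")
        if tid is None:
            raise ParseError("exon feature without transcript_id attribute", lineno)
        if tid not in exons:
            exons[tid] = []
            order.append(tid)
            strands[tid] = strand
            gene_ids[tid] = attr.get("gene_id")
            attrs[tid] = {
                k: v for k, v in attr.items() if k not in ("transcript_id", "gene_id")
            }
        try:
            # GTF is 1-based inclusive; internal model is 0-based half-open.
            exons[tid].append(ExonInterval(chrom, start1 - 1, end1, strand))
        except ValidationError as exc:
            raise ParseError(str(exc), lineno)
    out = []
    for tid in order:
        try:
            out.append(
                TranscriptModel(
                    transcript_id=tid,
                    exons=exons[tid],
                    strand=strands[tid],
                    gene_id=gene_ids[tid],
                    attributes=attrs[tid],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"transcript {tid!r}: {exc}")
    return out


def write_gtf(transcripts: Sequence[TranscriptModel], handle: Optional[TextIO] = None) -> str:
    """Serialize transcripts as GTF exon features, ordered by (chrom, start, id)."""
    lines = []
    for t in sorted_transcripts(transcripts):
        gene = t.gene_id if t.gene_id is not None else t.transcript_id
        extra = "".join(f' {k} "{v}";' for k, v in t.attributes.items())
        for exon in t.exons:
            attr = f'gene_id "{gene}"; transcript_id "{t.transcript_id}";{extra}'
            lines.append(
                "\t".join(
                    [
                        t.chrom,
                        "txrefine",
                        "exon",
                        str(exon.start + 1),
                        str(exon.end),
                        ".",
                        t.strand,
                        ".",
                        attr,
                    ]
                )
            )
    text = "\n".join(lines) + ("\n" if lines else "")
    if handle is not None:
        handle.write(text)
    return text


# ---------------------------------------------------------------------------
# VCF

_VCF_METRIC_KEYS = ("QD", "MQ", "FS", "HaplotypeScore", "MQRankSum", "ReadPosRankSum")


def parse_vcf(stream: Stream) -> List[VariantRecord]:
    """Parse a VCF 4.x text into VariantRecords (file order, one per site).

    Records without a GT field are kept with ``genotype=None``; the six INFO
    metrics used by the hard filters are extracted as floats when present.
    """
    handle = _as_handle(stream)
    records: List[VariantRecord] = []
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ParseError(f"expected >= 8 VCF columns, got {len(fields)}", lineno)
        chrom, pos_s, rid, ref, alt_s = fields[:5]
        info_s = fields[7]
        try:
            pos = int(pos_s)
        except ValueError:
            raise ParseError(f"non-integer POS {pos_s!r}", lineno)
        alts = alt_s.split(",")
        info_metrics: Dict[str, float] = {}
        for item in info_s.split(";"):
            if "=" not in item:
                continue
            key, _, value = item.partition("=")
            if key in _VCF_METRIC_KEYS:
                try:
                    info_metrics[key] = float(value)
                except ValueError:
                    raise ParseError(f"non-numeric INFO value {key}={value}", lineno)
        genotype = None
        depths = None
        if len(fields) >= 10:
            fmt_keys = fields[8].split(":")
            sample = fields[9].split(":")
            values = dict(zip(fmt_keys, sample))
            gt = values.get("GT")
            if gt and "." not in gt:
                alleles = re.split(r"[/|]", gt)
                if len(alleles) == 2:
                    try:
                        genotype = (int(alleles[0]), int(alleles[1]))
                    except ValueError:
                        raise ParseError(f"malformed GT {gt!r}", lineno)
            ad = values.get("AD")
            if ad and "." not in ad.split(","):
                try:
                    depths = [int(x) for x in ad.split(",")]
                except ValueError:
                    raise ParseError(f"malformed AD {ad!r}", lineno)
        try:
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_alleles=alts,
                    genotype=genotype,
                    info_metrics=info_metrics,
                    allele_depths=depths,
                    record_id=rid,
                )
            )
        except ValidationError as exc:
            raise ParseError(str(exc), lineno)
    return records


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=FS,Number=1,Type=Float,Description="Strand bias Fisher phred">
##INFO=<ID=HaplotypeScore,Number=1,Type=Float,Description="Haplotype consistency">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample
"""


def write_vcf(
    records: Sequence[VariantRecord],
    handle: Optional[TextIO] = None,
    filter_tags: Optional[Dict[int, str]] = None,
) -> str:
    """Serialize VariantRecords as a minimal single-sample VCF.

    ``filter_tags`` maps record index -> FILTER column content (used to write
    hard-filter failure reasons); untagged records get PASS.
    """
    lines = [_VCF_HEADER.rstrip("\n")]
    for i, rec in enumerate(records):
        info_items = [
            f"{k}={rec.info_metrics[k]:g}" for k in _VCF_METRIC_KEYS if k in rec.info_metrics
        ]
        info = ";".join(info_items) if info_items else "."
        if rec.genotype is None:
            gt = "./."
        else:
            gt = f"{rec.genotype[0]}/{rec.genotype[1]}"
        fmt, sample = "GT", gt
        if rec.allele_depths is not None:
            fmt = "GT:AD"
            sample = gt + ":" + ",".join(str(d) for d in rec.allele_depths)
        filt = filter_tags.get(i, "PASS") if filter_tags else "PASS"
        lines.append(
            "\t".join(
                [
                    rec.chrom,
                    str(rec.pos),
                    rec.record_id,
                    rec.ref_allele,
                    ",".join(rec.alt_alleles),
                    ".",
                    filt,
                    info,
                    fmt,
                    sample,
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if handle is not None:
        handle.write(text)
    return text


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def parse_fasta(stream: Stream) -> GenomeSequence:
    """Parse FASTA into {name: uppercase sequence}; rejects non-ACGTN bases."""
    handle = _as_handle(stream)
    genome: GenomeSequence = {}
    for record in SeqIO.parse(handle, "fasta"):
        name = record.id
        if name in genome:
            raise ValidationError(f"duplicate sequence name {name!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValidationError(f"empty sequence for {name!r}")
        genome[name] = seq
    validate_genome(genome)
    return genome


def write_fasta(sequences: Dict[str, str], handle: Optional[TextIO] = None, width: int = 70) -> str:
    lines = []
    for name, seq in sequences.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    text = "\n".join(lines) + ("\n" if lines else "")
    if handle is not None:
        handle.write(text)
    return text


def parse_fastq(stream: Stream) -> List[ReadRecord]:
    """Parse FASTQ (phred+33) into ReadRecords."""
    handle = _as_handle(stream)
    reads = []
    for record in SeqIO.parse(handle, "fastq"):
        quals = record.letter_annotations["phred_quality"]
        reads.append(
            ReadRecord(
                read_id=record.id,
                sequence=str(record.seq).upper(),
                quality="".join(chr(q + 33) for q in quals),
                quality_encoding="phred+33",
            )
        )
    return reads


def write_fastq(reads: Sequence[ReadRecord], handle: Optional[TextIO] = None) -> str:
    lines = []
    for r in reads:
        lines.extend([f"@{r.read_id}", r.sequence, "+", r.quality])
    text = "\n".join(lines) + ("\n" if lines else "")
    if handle is not None:
        handle.write(text)
    return text


# ---------------------------------------------------------------------------
# BED12

def parse_bed12(stream: Stream, source_label: str) -> AnnotationSet:
    """Parse BED12 gene structures into an AnnotationSet.

    Gene spans come from columns 1-3; introns are derived from the gaps
    between blocks, with strand from column 6.
    """
    handle = _as_handle(stream)
    gene_spans: List[Tuple[str, int, int, str]] = []
    introns = set()
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(f"expected 12 BED columns, got {len(fields)}", lineno)
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError:
            raise ParseError("malformed numeric BED12 field", lineno)
        name = fields[3]
        strand = fields[5]
        if len(sizes) != block_count or len(starts) != block_count:
            raise ParseError(
                f"blockCount {block_count} inconsistent with block lists", lineno
            )
        gene_spans.append((chrom, start, end, name))
        for i in range(block_count - 1):
            intron_start = start + starts[i] + sizes[i]
            intron_end = start + starts[i + 1]
            introns.add(IntronKey(chrom, intron_start, intron_end, strand))
    return AnnotationSet(source_label=source_label, gene_spans=gene_spans, introns=introns)


def bed12_line(transcript: TranscriptModel, name: Optional[str] = None) -> str:
    """Render one transcript/gene structure as a BED12 line."""
    start = transcript.span_start
    sizes = ",".join(str(e.length) for e in transcript.exons) + ","
    starts = ",".join(str(e.start - start) for e in transcript.exons) + ","
    return "\t".join(
        [
            transcript.chrom,
            str(start),
            str(transcript.span_end),
            name or transcript.transcript_id,
            "0",
            transcript.strand,
            str(start),
            str(transcript.span_end),
            "0",
            str(transcript.exon_count),
            sizes,
            starts,
        ]
    )


# ---------------------------------------------------------------------------
# Alignment-record TSV and junction TSV

def parse_alignment_tsv(stream: Stream) -> List["AlignmentRecord"]:
    """Plain-TSV alignment records: read_id, mate, chrom, pos, strand, mismatches."""
    from .models import AlignmentRecord

    handle = _as_handle(stream)
    records = []
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(f"expected 6 columns, got {len(fields)}", lineno)
        read_id, mate_s, chrom, pos_s, strand, mm_s = fields[:6]
        mate = None if mate_s in (".", "") else int(mate_s)
        records.append(
            AlignmentRecord(
                read_id=read_id,
                mate_index=mate,
                chrom=chrom,
                pos=int(pos_s),
                strand=strand,
                mismatch_count=int(mm_s),
            )
        )
    return records


def write_alignment_tsv(records: Iterable, handle: Optional[TextIO] = None) -> str:
    lines = ["#read_id\tmate\tchrom\tpos\tstrand\tmismatches"]
    for r in records:
        mate = "." if r.mate_index is None else str(r.mate_index)
        lines.append(
            f"{r.read_id}\t{mate}\t{r.chrom}\t{r.pos}\t{r.strand}\t{r.mismatch_count}"
        )
    text = "\n".join(lines) + "\n"
    if handle is not None:
        handle.write(text)
    return text


def parse_junction_tsv(stream: Stream) -> List["JunctionRecord"]:
    """BED-like junction records: chrom, donor_end, acceptor_start, name,
    support, strand, dinucleotides (e.g. GT-AG)."""
    from .linkmerge import JunctionRecord

    handle = _as_handle(stream)
    out = []
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 7:
            raise ParseError(f"expected 7 columns, got {len(fields)}", lineno)
        chrom, donor_s, acceptor_s, name, support_s, strand, dinuc = fields[:7]
        out.append(
            JunctionRecord(
                chrom=chrom,
                donor_end=int(donor_s),
                acceptor_start=int(acceptor_s),
                strand=strand,
                dinucleotides=dinuc,
                name=name,
                support=int(support_s),
            )
        )
    return out


def write_junction_tsv(junctions: Sequence, handle: Optional[TextIO] = None) -> str:
    lines = ["#chrom\tdonor_end\tacceptor_start\tname\tsupport\tstrand\tdinucleotides"]
    for j in junctions:
        lines.append(
            f"{j.chrom}\t{j.donor_end}\t{j.acceptor_start}\t{j.name}\t"
            f"{j.support}\t{j.strand}\t{j.dinucleotides}"
        )
    text = "\n".join(lines) + "\n"
    if handle is not None:
        handle.write(text)
    return text
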