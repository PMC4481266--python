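"""Shared genomic data model and coordinate conventions.

All internal coordinates are 0-based half-open.  GTF is serialized 1-based
inclusive at the I/O boundary, and VCF positions are kept 1-based (VCF
convention) inside :class:`VariantRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

GENOME_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


#: A genome is a mapping from chromosome name to an uppercase ACGTN string.
GenomeSequence = Dict[str, str]


class ValidationError(ValueError):
    """A record violated a structural invariant of the data model."""


def validate_genome(genome: GenomeSequence) -> GenomeSequence:
    for name, seq in genome.items():
        if not seq:
            raise ValidationError(f"chromosome {name!r} has an empty sequence")
        bad = set(seq) - GENOME_ALPHABET
        if bad:
            raise ValidationError(
                f"chromosome {name!r} contains invalid characters: {sorted(bad)}"
            )
    return genome


@dataclass(frozen=True, order=True)
class ExonInterval:
    """Genomic interval of one exon, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid exon interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class IntronKey:
    """Identity of one intron: chrom, first intronic base, end (exclusive), strand.

    Exact equality of these four fields is the unit of intron concordance.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid intron {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """An exon chain with strand on a genome; the unit being merged and filtered."""

    transcript_id: str
    exons: List[ExonInterval]
    strand: str = "."
    gene_id: Optional[str] = None
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(
                f"transcript {self.transcript_id!r} has no exons"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(
                f"transcript {self.transcript_id!r} has invalid strand {self.strand!r}"
            )
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValidationError(
                f"transcript {self.transcript_id!r} spans chromosomes {sorted(chroms)}"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = -1
        for exon in self.exons:
            if exon.start <= prev_end:
                # overlapping exons, or a zero-length intron
                raise ValidationError(
                    f"transcript {self.transcript_id!r} has overlapping/abutting exons"
                )
            prev_end = exon.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span_start(self) -> int:
        return self.exons[0].start

    @property
    def span_end(self) -> int:
        return self.exons[-1].end

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    def introns(self) -> List[IntronKey]:
        """Gaps between consecutive exons, carrying the transcript strand."""
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            out.append(IntronKey(self.chrom, left.end, right.start, self.strand))
        return out


def introns_of(transcript: TranscriptModel) -> List[IntronKey]:
    """Ordered introns of a transcript (count = exon_count - 1)."""
    return transcript.introns()


@dataclass
class AnnotationSet:
    """One annotation source: gene spans and its set of annotated introns."""

    source_label: str
    gene_spans: List[Tuple[str, int, int, str]] = field(default_factory=list)
    introns: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for chrom, start, end, _gene in self.gene_spans:
            if not (0 <= start < end):
                raise ValidationError(
                    f"invalid gene span {chrom}:{start}-{end} in {self.source_label}"
                )


VALID_BASES = set("ACGT")


@dataclass
class VariantRecord:
    """A VCF-style variant site (1-based pos) with genotype, metrics and depths.

    Multi-allelic sites are stored as one record; per-allele analyses iterate
    ``alt_alleles``.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: List[str]
    genotype: Optional[Tuple[int, int]] = None
    info_metrics: Dict[str, float] = field(default_factory=dict)
    allele_depths: Optional[List[int]] = None
    record_id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref_allele or set(self.ref_allele) - VALID_BASES:
            raise ValidationError(
                f"invalid REF allele {self.ref_allele!r} at {self.chrom}:{self.pos}"
            )
        if not self.alt_alleles:
            raise ValidationError(f"no ALT alleles at {self.chrom}:{self.pos}")
        for alt in self.alt_alleles:
            if not alt or set(alt) - VALID_BASES:
                raise ValidationError(
                    f"invalid ALT allele {alt!r} at {self.chrom}:{self.pos}"
                )
            if alt == self.ref_allele:
                raise ValidationError(
                    f"ALT equals REF at {self.chrom}:{self.pos}"
                )
        if self.allele_depths is not None:
            if len(self.allele_depths) != 1 + len(self.alt_alleles):
                raise ValidationError(
                    f"AD length mismatch at {self.chrom}:{self.pos}"
                )

    def allele_class(self, alt_index: int = 0) -> str:
        """Class of one REF->ALT change: snp, insertion, deletion or mixed."""
        alt = self.alt_alleles[alt_index]
        if len(self.ref_allele) == len(alt):
            return "snp" if len(alt) == 1 else "mixed"
        if len(alt) > len(self.ref_allele):
            return "insertion"
        return "deletion"

    @property
    def variant_class(self) -> str:
        """Record-level class; 'mixed' when alleles disagree in class."""
        classes = {self.allele_class(i) for i in range(len(self.alt_alleles))}
        if len(classes) == 1:
            return classes.pop()
        return "mixed"


@dataclass
class ReadRecord:
    """A sequencing read with per-base qualities."""

    read_id: str
    sequence: str
    quality: str
    quality_encoding: str = "phred+33"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValidationError(
                f"read {self.read_id!r}: sequence/quality length mismatch"
            )
        if self.quality_encoding not in ("phred+33", "phred+64"):
            raise ValidationError(
                f"unknown quality encoding {self.quality_encoding!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def phred_scores(self) -> List[int]:
        offset = 33 if self.quality_encoding == "phred+33" else 64
        return [ord(c) - offset for c in self.quality]


@dataclass
class AlignmentRecord:
    """A short-read alignment record (SAM-convention fields or plain TSV)."""

    read_id: str
    chrom: str
    pos: int  # 0-based
    strand: str
    mismatch_count: int
    mate_index: Optional[int] = None  # 0/1 for paired, None for single-end
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mismatch_count < 0:
            raise ValidationError("mismatch_count must be >= 0")
        if self.mate_index not in (None, 0, 1):
            raise ValidationError(f"invalid mate_index {self.mate_index!r}")


def transcript_sort_key(t: TranscriptModel) -> Tuple[str, int, str]:
    return (t.chrom, t.span_start, t.transcript_id)


def sorted_transcripts(transcripts: Sequence[TranscriptModel]) -> List[TranscriptModel]:
    return sorted(transcripts, key=transcript_sort_key)
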