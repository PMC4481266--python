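"""Spliced transcript sequences, per-variant ORF change, and reference-error calls.

A variant observed in RNA against the reference genome is applied to the
spliced transcript sequence it resides in; if the longest open reading frame
grows, and genomic resequencing of the reference individual shows the same
variant as homozygous, the "variant" is a candidate error in the reference
assembly itself.  Two mechanistic signatures are flagged: homopolymer slips
(the indel adds/removes a base identical to an adjacent base) and
intron-mimicking deletions (deletion length equals a nearby annotated
intron's length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .models import GenomeSequence, IntronKey, TranscriptModel, VariantRecord, revcomp
from . import variants as _variants

STOP_CODONS = ("TAA", "TAG", "TGA")


class VariantApplicationSkip(Exception):
    """A variant cannot be applied to this transcript; carries a reason code."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class TranscriptSequence:
    """Spliced sequence plus a bijective genomic<->transcript coordinate map."""

    transcript_id: str
    chrom: str
    strand_used: str
    sequence: str
    genomic_positions: Tuple[int, ...]  # genomic 0-based position of each offset

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.genomic_positions):
            raise ValueError("sequence/coordinate map length mismatch")
        self._offset_of = {g: i for i, g in enumerate(self.genomic_positions)}

    def __len__(self) -> int:
        return len(self.sequence)

    def offset_of(self, genomic_pos: int) -> Optional[int]:
        return self._offset_of.get(genomic_pos)


def build_transcript_sequence(
    transcript: TranscriptModel, genome: GenomeSequence
) -> TranscriptSequence:
    """Concatenate exon sequences 5'->3'; '-' strand is reverse-complemented.

    Strandless ('.') transcripts use the forward genomic orientation; the ORF
    scan covers both strands downstream.
    """
    chrom_seq = genome.get(transcript.chrom)
    if chrom_seq is None:
        raise KeyError(f"chromosome {transcript.chrom!r} not in genome")
    parts: List[str] = []
    positions: List[int] = []
    for exon in transcript.exons:
        if exon.end > len(chrom_seq):
            raise ValueError(
                f"exon {exon.chrom}:{exon.start}-{exon.end} outside chromosome bounds"
            )
        parts.append(chrom_seq[exon.start : exon.end])
        positions.extend(range(exon.start, exon.end))
    seq = "".join(parts)
    if transcript.strand == "-":
        seq = revcomp(seq)
        positions = positions[::-1]
    return TranscriptSequence(
        transcript_id=transcript.transcript_id,
        chrom=transcript.chrom,
        strand_used=transcript.strand,
        sequence=seq,
        genomic_positions=tuple(positions),
    )


def map_genomic_to_transcript(ts: TranscriptSequence, genomic_pos: int) -> Optional[int]:
    """Transcript offset of an exonic genomic position; None when non-exonic."""
    return ts.offset_of(genomic_pos)


def apply_variant_to_transcript(
    ts: TranscriptSequence, variant: VariantRecord, alt_index: int = 0
) -> str:
    """Spliced sequence with one REF->ALT change applied.

    All reference bases touched by the variant must be exonic in this
    transcript; partial overlap with an exon boundary raises a skip with
    reason ``boundary_overlap``, a fully intronic/outside variant with
    reason ``not_exonic``.  On '-' strand transcripts the reverse complement
    of the allele change is applied.
    """
    ref = variant.ref_allele
    alt = variant.alt_alleles[alt_index]
    g0 = variant.pos - 1
    offsets = [ts.offset_of(g0 + i) for i in range(len(ref))]
    if all(o is None for o in offsets):
        raise VariantApplicationSkip("not_exonic")
    if any(o is None for o in offsets):
        raise VariantApplicationSkip("boundary_overlap")
    if ts.strand_used == "-":
        t_start = min(offsets)
        ref_t = revcomp(ref)
        alt_t = revcomp(alt)
    else:
        t_start = offsets[0]
        ref_t = ref
        alt_t = alt
    observed = ts.sequence[t_start : t_start + len(ref)]
    if observed != ref_t:
        raise VariantApplicationSkip("reference_mismatch")
    return ts.sequence[:t_start] + alt_t + ts.sequence[t_start + len(ref) :]


@dataclass(frozen=True)
class OrfResult:
    """One open reading frame: ATG through stop codon, inclusive."""

    strand: str  # 'forward' or 'reverse'
    frame: int
    start: int  # offset within the scanned strand's sequence
    end: int  # exclusive, includes the stop codon
    length: int

    def __post_init__(self) -> None:
        if self.length % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")


def _scan_orfs(seq: str, strand: str) -> Iterable[OrfResult]:
    n = len(seq)
    for frame in range(3):
        open_start: Optional[int] = None
        for p in range(frame, n - 2, 3):
            codon = seq[p : p + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = p
            elif codon in STOP_CODONS:
                yield OrfResult(strand, frame, open_start, p + 3, p + 3 - open_start)
                open_start = None


def longest_orf(
    sequence: str, scan_both_strands: bool = True, mode: str = "atg_to_stop"
) -> Optional[OrfResult]:
    """Maximal-length complete ORF over 3 (or 6) frames.

    Default mode counts ATG through stop codon inclusive; ORFs truncated by
    the sequence end are not counted.  ``stop_to_stop`` mode instead measures
    maximal stop-free codon runs (sensitivity-analysis variant).  Ties break
    to the forward strand, then the smaller start offset.
    """
    sequence = sequence.upper()
    strands = [("forward", sequence)]
    if scan_both_strands:
        strands.append(("reverse", revcomp(sequence)))
    best: Optional[OrfResult] = None
    for strand, seq in strands:
        if mode == "atg_to_stop":
            candidates = _scan_orfs(seq, strand)
        elif mode == "stop_to_stop":
            candidates = _scan_stop_to_stop(seq, strand)
        else:
            raise ValueError(f"unknown ORF mode {mode!r}")
        for orf in candidates:
            if (
                best is None
                or orf.length > best.length
                or (
                    orf.length == best.length
                    and best.strand == "reverse"
                    and orf.strand == "forward"
                )
                or (
                    orf.length == best.length
                    and orf.strand == best.strand
                    and orf.start < best.start
                )
            ):
                best = orf
    return best


def _scan_stop_to_stop(seq: str, strand: str) -> Iterable[OrfResult]:
    n = len(seq)
    for frame in range(3):
        run_start = frame
        p = frame
        while p <= n - 3:
            if seq[p : p + 3] in STOP_CODONS:
                if p > run_start:
                    yield OrfResult(strand, frame, run_start, p, p - run_start)
                run_start = p + 3
            p += 3
        if p > run_start:
            yield OrfResult(strand, frame, run_start, p, p - run_start)


@dataclass
class OrfEffect:
    """Longest-ORF change caused by applying one variant to one transcript."""

    variant_key: Tuple[str, int, str, str]  # normalized (chrom, pos, ref, alt)
    variant_id: str
    transcript_id: str
    variant_class: str
    longest_orf_ref: int
    longest_orf_alt: int

    @property
    def effect(self) -> str:
        if self.longest_orf_alt > self.longest_orf_ref:
            return "extending"
        if self.longest_orf_alt < self.longest_orf_ref:
            return "shortening"
        return "neutral"


def classify_orf_effect(
    ts: TranscriptSequence,
    variant: VariantRecord,
    genome: Optional[GenomeSequence] = None,
    alt_index: int = 0,
    scan_both_strands: bool = True,
) -> OrfEffect:
    """Compare the longest ORF of the original and variant-applied sequence."""
    alt_seq = apply_variant_to_transcript(ts, variant, alt_index)
    ref_orf = longest_orf(ts.sequence, scan_both_strands)
    alt_orf = longest_orf(alt_seq, scan_both_strands)
    if genome is not None:
        key = _variants.normalize_allele(
            genome, variant.chrom, variant.pos, variant.ref_allele,
            variant.alt_alleles[alt_index],
        )
        variant_key = (variant.chrom,) + key
    else:
        variant_key = (
            variant.chrom,
            variant.pos,
            variant.ref_allele,
            variant.alt_alleles[alt_index],
        )
    return OrfEffect(
        variant_key=variant_key,
        variant_id=variant.record_id,
        transcript_id=ts.transcript_id,
        variant_class=variant.allele_class(alt_index),
        longest_orf_ref=ref_orf.length if ref_orf else 0,
        longest_orf_alt=alt_orf.length if alt_orf else 0,
    )


@dataclass
class ReferenceErrorCall:
    """Support classification of one ORF-extending variant."""

    variant_key: Tuple[str, int, str, str]
    variant_id: str
    transcript_id: str
    variant_class: str
    support_class: str  # homozygous / heterozygous / unsupported
    homopolymer_slip: bool = False
    intron_mimic: bool = False

    @property
    def is_candidate_error(self) -> bool:
        return self.support_class == "homozygous"


def classify_error_mechanism(
    variant: VariantRecord,
    genome: GenomeSequence,
    annotation_introns: Iterable[IntronKey],
    tolerance: int = 10,
    alt_index: int = 0,
) -> Tuple[bool, bool]:
    """Mechanistic flags for one (normalized) variant allele.

    homopolymer_slip: every inserted/deleted base equals the genomic base
    immediately adjacent to the event (either flank).  intron_mimic: some
    annotated intron has the same length as the deletion and a start within
    ``tolerance`` bp of the deletion start.  SNPs get (False, False).
    """
    pos, ref, alt = _variants.normalize_allele(
        genome, variant.chrom, variant.pos, variant.ref_allele,
        variant.alt_alleles[alt_index],
    )
    if len(ref) == len(alt):
        return False, False
    chrom_seq = genome[variant.chrom]
    if len(ref) > len(alt):  # deletion: event bases are ref minus the anchor
        event = ref[1:]
        left = chrom_seq[pos - 1]  # anchor base
        right_idx = pos - 1 + len(ref)
        del_start = pos  # 0-based first deleted base == 1-based anchor pos
        del_len = len(event)
    else:  # insertion between pos and pos+1
        event = alt[1:]
        left = chrom_seq[pos - 1]
        right_idx = pos
        del_start = None
        del_len = None
    right = chrom_seq[right_idx] if right_idx < len(chrom_seq) else ""
    uniform = len(set(event)) == 1
    slip = uniform and (event[0] == left or event[0] == right)

    mimic = False
    if del_start is not None:
        for intron in annotation_introns:
            if intron.chrom != variant.chrom:
                continue
            if intron.length == del_len and abs(intron.start - del_start) <= tolerance:
                mimic = True
                break
    return slip, mimic


def call_reference_errors(
    effects: Sequence[OrfEffect],
    genomic_passing: Sequence[VariantRecord],
    genome: Optional[GenomeSequence] = None,
    annotation_introns: Optional[Iterable[IntronKey]] = None,
    tolerance: int = 10,
) -> List[ReferenceErrorCall]:
    """Classify every extending effect by genomic resequencing support.

    homozygous when a matching passing genomic record is GT hom-alt,
    heterozygous when mixed-allele, unsupported otherwise.  Matching reuses
    allele normalization so RNA- and DNA-side representations of the same
    homopolymer indel compare equal.  When genome and annotation introns are
    supplied, mechanism flags are filled in.
    """
    support: Dict[Tuple[str, int, str, str], str] = {}
    rank = {"homozygous_alt": 2, "mixed_allele": 1}
    for rec in genomic_passing:
        category = _variants.classify_genotype_position(rec)
        if category not in rank:
            continue
        for i in range(len(rec.alt_alleles)):
            if rec.genotype is not None and (i + 1) not in rec.genotype:
                continue
            if genome is not None:
                key = (rec.chrom,) + _variants.normalize_allele(
                    genome, rec.chrom, rec.pos, rec.ref_allele, rec.alt_alleles[i]
                )
            else:
                key = (rec.chrom, rec.pos, rec.ref_allele, rec.alt_alleles[i])
            if rank.get(category, 0) > rank.get(support.get(key, ""), 0):
                support[key] = category
    introns = list(annotation_introns) if annotation_introns is not None else []
    calls: List[ReferenceErrorCall] = []
    for eff in effects:
        if eff.effect != "extending":
            continue
        category = support.get(eff.variant_key)
        if category == "homozygous_alt":
            support_class = "homozygous"
        elif category == "mixed_allele":
            support_class = "heterozygous"
        else:
            support_class = "unsupported"
        slip = mimic = False
        if genome is not None:
            chrom, pos, ref, alt = eff.variant_key
            rec = VariantRecord(chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=[alt])
            slip, mimic = classify_error_mechanism(rec, genome, introns, tolerance)
        calls.append(
            ReferenceErrorCall(
                variant_key=eff.variant_key,
                variant_id=eff.variant_id,
                transcript_id=eff.transcript_id,
                variant_class=eff.variant_class,
                support_class=support_class,
                homopolymer_slip=slip,
                intron_mimic=mimic,
            )
        )
    return calls
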