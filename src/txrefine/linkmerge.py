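"""Merging fragmented transcript assemblies with long-read end-segment links
and non-canonical splice junctions.

Long reads are reduced to 2x25 bp end segments, aligned exhaustively to the
spliced transcript sequences (<= 1 mismatch, discarded above 3 placements);
a read whose two segments land in two different transcripts in proper
orientation on the same genomic strand, with the transcripts within 200 kb,
is a link candidate.  The full read is then split-aligned across the gap by
brute force over split positions; the implied intron is accepted only when
an annotated intron agrees within a 10 bp tolerance at both the donor and
the acceptor.  Accepted links (plus non-canonical-junction connections) are
applied as connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .models import (
    ExonInterval,
    GenomeSequence,
    IntronKey,
    TranscriptModel,
    revcomp,
)
from .orf import TranscriptSequence
from .reads import SEGMENT_LENGTH, SegmentPair

CANONICAL_DINUCLEOTIDES = "GT-AG"


@dataclass(frozen=True)
class SegmentHit:
    """One <= 1-mismatch placement of a 25 bp segment in a transcript."""

    segment_id: str
    target_transcript_id: str
    offset: int
    strand: str  # '+' forward, '-' reverse-complement placement
    mismatches: int


@dataclass
class SegmentAlignment:
    """All kept hits for one segment; empty when unmapped or multimapped."""

    segment_id: str
    hits: List[SegmentHit] = field(default_factory=list)
    multimapped: bool = False


def align_segment(
    segment_seq: str,
    segment_id: str,
    transcript_sequences: Dict[str, str],
    max_hits: int = 3,
    max_mismatches: int = 1,
) -> SegmentAlignment:
    """Exhaustively place a 25 bp segment in every transcript, both orientations.

    All placements with <= ``max_mismatches`` are found; when more than
    ``max_hits`` locations exist the segment is discarded entirely
    (suppression semantics) and flagged multimapped.
    """
    if len(segment_seq) != SEGMENT_LENGTH:
        raise ValueError(f"segment must be {SEGMENT_LENGTH} bp, got {len(segment_seq)}")
    queries = {
        "+": np.frombuffer(segment_seq.encode("ascii"), dtype=np.uint8),
        "-": np.frombuffer(revcomp(segment_seq).encode("ascii"), dtype=np.uint8),
    }
    hits: List[SegmentHit] = []
    for tid in sorted(transcript_sequences):
        seq = transcript_sequences[tid]
        if len(seq) < SEGMENT_LENGTH:
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, SEGMENT_LENGTH)
        for strand, query in queries.items():
            mismatches = (windows != query).sum(axis=1)
            for offset in np.nonzero(mismatches <= max_mismatches)[0]:
                hits.append(
                    SegmentHit(
                        segment_id=segment_id,
                        target_transcript_id=tid,
                        offset=int(offset),
                        strand=strand,
                        mismatches=int(mismatches[offset]),
                    )
                )
    if len(hits) > max_hits:
        return SegmentAlignment(segment_id=segment_id, hits=[], multimapped=True)
    return SegmentAlignment(segment_id=segment_id, hits=hits)


@dataclass(frozen=True)
class LinkCandidate:
    """A read whose two end segments hit two linkable transcripts.

    ``transcript_a_id`` is the genomically left transcript.  Candidates are
    only emitted when orientation and strand checks pass and the genomic gap
    is within the window, so both flags are True by construction.
    """

    read_id: str
    transcript_a_id: str
    transcript_b_id: str
    genomic_gap: int
    orientation_ok: bool = True
    same_strand: bool = True


def _transcript_upstream_is_left(strand: str) -> bool:
    # For '+' (and strandless) transcripts the 5' end is the genomic left.
    return strand != "-"


def find_link_candidates(
    segment_alignments: Dict[str, Tuple[SegmentAlignment, SegmentAlignment]],
    transcripts: Dict[str, TranscriptModel],
    max_gap: int = 200_000,
) -> List[LinkCandidate]:
    """Candidates from reads whose 5' and 3' segments hit different transcripts.

    Required: same chromosome and compatible genomic strand, both segments
    placed in the same orientation, proper orientation (the 5' segment hits
    the transcript that is upstream in the direction of transcription,
    accounting for a possibly reverse-complemented read), non-overlapping
    spans, and a genomic gap <= ``max_gap``.
    """
    candidates: List[LinkCandidate] = []
    seen: Set[Tuple[str, str, str]] = set()
    for read_id in sorted(segment_alignments):
        aln5, aln3 = segment_alignments[read_id]
        for h5 in aln5.hits:
            for h3 in aln3.hits:
                if h5.target_transcript_id == h3.target_transcript_id:
                    continue
                if h5.strand != h3.strand:
                    continue
                t5 = transcripts[h5.target_transcript_id]
                t3 = transcripts[h3.target_transcript_id]
                if t5.chrom != t3.chrom:
                    continue
                if not (t5.strand == t3.strand or "." in (t5.strand, t3.strand)):
                    continue
                strand = t5.strand if t5.strand != "." else t3.strand
                # Transcript-flow order: forward-placed segments read 5'->3'
                # along the mRNA, so the 5' segment's transcript is upstream;
                # a reverse-complemented read swaps the roles.
                upstream, downstream = (t5, t3) if h5.strand == "+" else (t3, t5)
                if _transcript_upstream_is_left(strand):
                    left, right = upstream, downstream
                else:
                    left, right = downstream, upstream
                gap = right.span_start - left.span_end
                if gap < 0 or gap > max_gap:
                    continue
                key = (read_id, left.transcript_id, right.transcript_id)
                if key in seen:
                    continue
                seen.add(key)
                candidates.append(
                    LinkCandidate(
                        read_id=read_id,
                        transcript_a_id=left.transcript_id,
                        transcript_b_id=right.transcript_id,
                        genomic_gap=gap,
                    )
                )
    return candidates


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction with its donor/acceptor dinucleotides."""

    chrom: str
    donor_end: int  # 0-based exclusive end of the upstream exon
    acceptor_start: int  # 0-based start of the downstream exon
    strand: str
    dinucleotides: str  # e.g. "GT-AG"
    name: str = "."
    support: int = 0

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValueError("junction donor must precede acceptor")

    @property
    def canonical(self) -> bool:
        return self.dinucleotides == CANONICAL_DINUCLEOTIDES


def junction_dinucleotides(
    genome: GenomeSequence, chrom: str, donor_end: int, acceptor_start: int, strand: str
) -> str:
    """Intron-terminal dinucleotides in transcription orientation (e.g. GT-AG)."""
    seq = genome[chrom]
    first = seq[donor_end : donor_end + 2]
    last = seq[acceptor_start - 2 : acceptor_start]
    if strand == "-":
        first, last = revcomp(last), revcomp(first)
    return f"{first}-{last}"


@dataclass
class MergeResult:
    """One accepted pairwise connection between two transcripts."""

    transcript_a_id: str
    transcript_b_id: str
    linking_intron: IntronKey
    supporting_read_ids: List[str] = field(default_factory=list)
    mechanism: str = "read_link"  # or "noncanonical_junction"


@dataclass
class LinkRejection:
    read_id: str
    transcript_a_id: str
    transcript_b_id: str
    reason: str


def refine_link(
    full_read_seq: str,
    genome: GenomeSequence,
    candidate: LinkCandidate,
    transcript_sequences: Dict[str, TranscriptSequence],
    transcripts: Dict[str, TranscriptModel],
    annotation_introns: Iterable[IntronKey],
    tolerance: int = 10,
    max_total_mismatches: int = 5,
):
    """Split-align the full read across the gap and vet the implied intron.

    Brute force over split positions: the read prefix is aligned to the 3'
    end of the upstream transcript's spliced sequence, the suffix to the 5'
    start of the downstream one, minimizing total mismatches (both read
    orientations are tried).  The implied intron — the genomic gap between
    the left transcript's last exon and the right one's first exon — is
    accepted only when some annotated intron on the chromosome agrees within
    ``tolerance`` bp at the donor AND the acceptor.  Returns a MergeResult or
    a LinkRejection.
    """
    left = transcripts[candidate.transcript_a_id]
    right = transcripts[candidate.transcript_b_id]
    strand = left.strand if left.strand != "." else right.strand
    if _transcript_upstream_is_left(strand):
        upstream, downstream = left, right
    else:
        upstream, downstream = right, left
    u_seq = transcript_sequences[upstream.transcript_id].sequence
    d_seq = transcript_sequences[downstream.transcript_id].sequence

    best = None
    for read in (full_read_seq, revcomp(full_read_seq)):
        n = len(read)
        for split in range(1, n):
            prefix, suffix = read[:split], read[split:]
            if len(prefix) > len(u_seq) or len(suffix) > len(d_seq):
                continue
            mm = sum(
                1 for a, b in zip(prefix, u_seq[len(u_seq) - len(prefix) :]) if a != b
            )
            if best is not None and mm >= best:
                continue
            mm += sum(1 for a, b in zip(suffix, d_seq[: len(suffix)]) if a != b)
            if best is None or mm < best:
                best = mm
    if best is None or best > max_total_mismatches:
        return LinkRejection(
            candidate.read_id,
            candidate.transcript_a_id,
            candidate.transcript_b_id,
            "no_spliced_alignment",
        )

    implied = IntronKey(left.chrom, left.span_end, right.span_start, strand)
    supported = any(
        intron.chrom == implied.chrom
        and abs(intron.start - implied.start) <= tolerance
        and abs(intron.end - implied.end) <= tolerance
        for intron in annotation_introns
    )
    if not supported:
        return LinkRejection(
            candidate.read_id,
            candidate.transcript_a_id,
            candidate.transcript_b_id,
            "intron_not_annotated",
        )
    return MergeResult(
        transcript_a_id=left.transcript_id,
        transcript_b_id=right.transcript_id,
        linking_intron=implied,
        supporting_read_ids=[candidate.read_id],
    )


def merge_by_noncanonical_junction(
    transcripts: Sequence[TranscriptModel],
    junctions: Sequence[JunctionRecord],
) -> Tuple[List[MergeResult], List[str]]:
    """Connect transcripts joined end-to-start by a non-canonical junction.

    A merge requires the junction's donor to coincide exactly with the end of
    one transcript's last exon and its acceptor with the start of another's
    first exon, on the same chromosome with compatible strands.  Ambiguous
    attachments (several transcripts sharing the boundary) are logged and
    skipped; canonical (GT-AG) junctions are ignored by this operation.
    """
    donors: Dict[Tuple[str, int], List[TranscriptModel]] = {}
    acceptors: Dict[Tuple[str, int], List[TranscriptModel]] = {}
    for t in transcripts:
        donors.setdefault((t.chrom, t.span_end), []).append(t)
        acceptors.setdefault((t.chrom, t.span_start), []).append(t)
    results: List[MergeResult] = []
    log: List[str] = []
    for j in junctions:
        if j.canonical:
            continue
        ds = donors.get((j.chrom, j.donor_end), [])
        accs = acceptors.get((j.chrom, j.acceptor_start), [])
        ds = [t for t in ds if _strand_ok(t.strand, j.strand)]
        accs = [t for t in accs if _strand_ok(t.strand, j.strand)]
        if not ds or not accs:
            continue
        if len(ds) > 1 or len(accs) > 1:
            log.append(f"ambiguous junction {j.chrom}:{j.donor_end}-{j.acceptor_start}")
            continue
        a, b = ds[0], accs[0]
        if a.transcript_id == b.transcript_id:
            continue
        results.append(
            MergeResult(
                transcript_a_id=a.transcript_id,
                transcript_b_id=b.transcript_id,
                linking_intron=IntronKey(j.chrom, j.donor_end, j.acceptor_start, j.strand),
                mechanism="noncanonical_junction",
            )
        )
    return results, log


def _strand_ok(t_strand: str, j_strand: str) -> bool:
    return t_strand == j_strand or "." in (t_strand, j_strand)


def apply_merges(
    transcripts: Sequence[TranscriptModel],
    merges: Sequence[MergeResult],
) -> Tuple[List[TranscriptModel], Dict[str, List[str]]]:
    """Apply accepted connections as connected components.

    Transitively linked transcripts collapse into one merged model whose exon
    set is the union of the sources' exons (overlapping or abutting exons are
    joined, so no exonic base is lost).  Returns the new transcript list and
    a provenance map merged_id -> source ids.
    """
    txs = list(transcripts)
    index = {t.transcript_id: i for i, t in enumerate(txs)}
    uf = _UnionFindById(len(txs))
    for m in merges:
        if m.transcript_a_id in index and m.transcript_b_id in index:
            uf.union(index[m.transcript_a_id], index[m.transcript_b_id])
    components: Dict[int, List[TranscriptModel]] = {}
    for i, t in enumerate(txs):
        components.setdefault(uf.find(i), []).append(t)

    merged: List[TranscriptModel] = []
    provenance: Dict[str, List[str]] = {}
    for group in components.values():
        if len(group) == 1:
            merged.append(group[0])
            continue
        group = sorted(group, key=lambda t: t.span_start)
        exons = _union_exons([e for t in group for e in t.exons])
        strands = {t.strand for t in group} - {"."}
        strand = strands.pop() if len(strands) == 1 else "."
        new_id = "+".join(t.transcript_id for t in group)
        gene_ids = {t.gene_id for t in group if t.gene_id}
        merged.append(
            TranscriptModel(
                transcript_id=new_id,
                exons=[ExonInterval(group[0].chrom, s, e, strand) for s, e in exons],
                strand=strand,
                gene_id=gene_ids.pop() if len(gene_ids) == 1 else None,
            )
        )
        provenance[new_id] = [t.transcript_id for t in group]
    merged.sort(key=lambda t: (t.chrom, t.span_start, t.transcript_id))
    return merged, provenance


def _union_exons(exons: Sequence[ExonInterval]) -> List[Tuple[int, int]]:
    ivs = sorted((e.start, e.end) for e in exons)
    out: List[Tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class _UnionFindById:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
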