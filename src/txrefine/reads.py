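"""Read trimming, alignment-record filtering, and long-read end-segment prep.

Short reads are end-trimmed for N bases and 'B'-tail quality characters (the
Illumina-1.5 read-segment marker), then adapter-trimmed at the 3' end.  Long
reads (>= 50 nt) are converted to 2x25 bp end-segment pairs for linking
fragmented transcript assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .models import AlignmentRecord, ReadRecord

SEGMENT_LENGTH = 25


def trim_read_ends(read: ReadRecord) -> ReadRecord:
    """Remove maximal 5' and 3' runs of bases that are N or quality 'B'.

    Interior positions are untouched; a fully trimmed read comes back with an
    empty sequence (the caller's signal to drop it).  Idempotent.
    """
    bad = [b == "N" or q == "B" for b, q in zip(read.sequence, read.quality)]
    start = 0
    while start < len(bad) and bad[start]:
        start += 1
    end = len(bad)
    while end > start and bad[end - 1]:
        end -= 1
    return ReadRecord(
        read_id=read.read_id,
        sequence=read.sequence[start:end],
        quality=read.quality[start:end],
        quality_encoding=read.quality_encoding,
    )


def trim_adapter_3p(read: ReadRecord, adapter: str, min_overlap: int = 5) -> ReadRecord:
    """Remove the longest read suffix that exactly matches a prefix of the adapter.

    Only overlaps of at least ``min_overlap`` bases are trimmed; quality is
    trimmed in lockstep.
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    max_len = min(len(read.sequence), len(adapter))
    for overlap in range(max_len, min_overlap - 1, -1):
        if read.sequence.endswith(adapter[:overlap]):
            return ReadRecord(
                read_id=read.read_id,
                sequence=read.sequence[: len(read.sequence) - overlap],
                quality=read.quality[: len(read.quality) - overlap],
                quality_encoding=read.quality_encoding,
            )
    return read


@dataclass
class AlignmentFilterStats:
    dropped_mismatches: int = 0
    dropped_improper_pair: int = 0
    dropped_orphan: int = 0
    kept: int = 0


def filter_alignments(
    records: Sequence[AlignmentRecord],
    max_mismatches: int = 3,
    insert_min: int = 1,
    insert_max: int = 500_000,
) -> Tuple[List[AlignmentRecord], AlignmentFilterStats]:
    """Drop records with > ``max_mismatches`` and improper pairs.

    A pair is kept only when both mates pass the mismatch rule, map to the
    same chromosome on opposite strands, and their 5'-to-5' span lies within
    ``[insert_min, insert_max]``.  Orphan mates are dropped and counted.
    Output order follows input order; the filter never adds records.
    """
    stats = AlignmentFilterStats()
    pairs: Dict[str, Dict[int, AlignmentRecord]] = {}
    for rec in records:
        if rec.mate_index is not None:
            pairs.setdefault(rec.read_id, {})[rec.mate_index] = rec

    keep_ids = set()
    for read_id, mates in pairs.items():
        if len(mates) != 2:
            stats.dropped_orphan += len(mates)
            continue
        a, b = mates[0], mates[1]
        if a.mismatch_count > max_mismatches or b.mismatch_count > max_mismatches:
            stats.dropped_mismatches += 2
            continue
        span = abs(a.pos - b.pos)
        proper = (
            a.chrom == b.chrom
            and a.strand != b.strand
            and insert_min <= span <= insert_max
        )
        if proper:
            keep_ids.add(read_id)
        else:
            stats.dropped_improper_pair += 2

    kept: List[AlignmentRecord] = []
    for rec in records:
        if rec.mate_index is None:
            if rec.mismatch_count > max_mismatches:
                stats.dropped_mismatches += 1
            else:
                kept.append(rec)
        elif rec.read_id in keep_ids:
            kept.append(rec)
    stats.kept = len(kept)
    return kept, stats


@dataclass
class SegmentPair:
    """First and last 25 bp of one long read, treated as a paired-end read."""

    source_read_id: str
    segment5: ReadRecord
    segment3: ReadRecord

    def __post_init__(self) -> None:
        if len(self.segment5) != SEGMENT_LENGTH or len(self.segment3) != SEGMENT_LENGTH:
            raise ValueError("segments must be exactly 25 bp")


@dataclass
class SegmentPrepStats:
    skipped_short: int = 0
    skipped_quality: int = 0
    emitted: int = 0


def _segment_quality_ok(segment: ReadRecord, min_quality: float, mode: str) -> bool:
    scores = segment.phred_scores()
    if mode == "mean":
        return sum(scores) / len(scores) >= min_quality
    if mode == "min":
        return min(scores) >= min_quality
    raise ValueError(f"unknown quality mode {mode!r}")


def prepare_segment_pairs(
    long_reads: Sequence[ReadRecord],
    min_length: int = 50,
    min_quality: float = 28.0,
    quality_mode: str = "mean",
) -> Tuple[List[SegmentPair], SegmentPrepStats]:
    """Convert long reads into 2x25 bp end-segment pairs.

    Reads shorter than ``min_length`` are skipped; a pair is skipped when
    either segment's quality (mean phred by default, per-base min optionally)
    falls below ``min_quality`` (boundary inclusive: >= is kept).
    """
    stats = SegmentPrepStats()
    pairs: List[SegmentPair] = []
    for read in long_reads:
        n = len(read)
        if n < min_length:
            stats.skipped_short += 1
            continue
        seg5 = ReadRecord(
            read_id=read.read_id + "/5p",
            sequence=read.sequence[:SEGMENT_LENGTH],
            quality=read.quality[:SEGMENT_LENGTH],
            quality_encoding=read.quality_encoding,
        )
        seg3 = ReadRecord(
            read_id=read.read_id + "/3p",
            sequence=read.sequence[n - SEGMENT_LENGTH :],
            quality=read.quality[n - SEGMENT_LENGTH :],
            quality_encoding=read.quality_encoding,
        )
        if not (
            _segment_quality_ok(seg5, min_quality, quality_mode)
            and _segment_quality_ok(seg3, min_quality, quality_mode)
        ):
            stats.skipped_quality += 1
            continue
        pairs.append(SegmentPair(read.read_id, seg5, seg3))
    stats.emitted = len(pairs)
    return pairs, stats
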