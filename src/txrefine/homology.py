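"""Local alignment scoring with bit-score conversion and evidence filtering.

Single- and two-exon transcript assemblies are notoriously enriched for
mapping artefacts, so they are kept only when they show similarity (best
local-alignment bit score >= a cutoff, 400 bits by default) to an evidence
database of pooled long reads and coding sequences.  The aligner is an exact
affine-gap Smith-Waterman; the bit-score conversion is the Karlin-Altschul
rescaling bits = (lambda * S - ln K) / ln 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models import TranscriptModel


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scoring plus Karlin-Altschul lambda and K.

    The default lambda/K values are documented approximations for the
    +1/-2 nucleotide scheme; all constants are configuration, not contract.
    A gap of length L costs ``-(gap_open) + L * -(gap_extend)`` score units.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 1.28
    K: float = 0.46

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0 or self.gap_open > 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")
        if self.lam <= 0 or not (0 < self.K < 1):
            raise ValueError("require lambda > 0 and 0 < K < 1")


DEFAULT_SCHEME = ScoringScheme()

_N_CODE = ord("N")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def local_align_score(seq_a: str, seq_b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Maximal Smith-Waterman local alignment score with affine gaps.

    N never counts as a match (an N against anything scores as a mismatch).
    Returns 0 when no positive-scoring local alignment exists or either
    sequence is empty.

    The row recurrence vectorizes the horizontal-gap state with a running
    maximum: because opening a new gap immediately after closing one is never
    cheaper than extending the existing gap (gap_open <= 0), the in-row gap
    state E[j] equals max_{k<j}(G[k] - open - ext*(j-k)) over the non-gap
    candidates G, which is a prefix scan.
    """
    if not seq_a or not seq_b:
        return 0
    a = _encode(seq_a)
    b = _encode(seq_b)
    n = b.size
    match = np.int64(scheme.match)
    mismatch = np.int64(scheme.mismatch)
    open_pen = -np.int64(scheme.gap_open)
    ext_pen = -np.int64(scheme.gap_extend)
    neg_inf = np.int64(-(1 << 60))

    idx = np.arange(n + 1, dtype=np.int64)
    h_prev = np.zeros(n + 1, dtype=np.int64)
    f_prev = np.full(n + 1, neg_inf, dtype=np.int64)
    b_is_n = b == _N_CODE
    best = np.int64(0)
    for ai in a:
        sub = np.where((b == ai) & ~b_is_n & (ai != _N_CODE), match, mismatch)
        diag = h_prev[:-1] + sub
        f = np.maximum(f_prev[1:] - ext_pen, h_prev[1:] - open_pen - ext_pen)
        g = np.maximum(0, np.maximum(diag, f))
        g_full = np.concatenate(([np.int64(0)], g))
        scan = np.maximum.accumulate(g_full + ext_pen * idx)
        e = scan[:-1] - open_pen - ext_pen * idx[1:]
        h = np.maximum(g, e)
        row_best = h.max()
        if row_best > best:
            best = row_best
        h_prev = np.concatenate(([np.int64(0)], h))
        f_prev = np.concatenate(([neg_inf], f))
    return int(best)


def bit_score(raw_score: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Karlin-Altschul bit score: (lambda * S - ln K) / ln 2; 0 for S = 0."""
    if raw_score < 0:
        raise ValueError("raw score must be >= 0")
    if raw_score == 0:
        return 0.0
    return (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2)


@dataclass
class EvidenceHit:
    """Best evidence hit for one query transcript."""

    query_id: str
    subject_id: Optional[str]
    raw_score: int
    bits: float


def filter_low_evidence(
    transcripts: Sequence[TranscriptModel],
    transcript_sequences: Dict[str, str],
    evidence_sequences: Dict[str, str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    threshold_bits: float = 400.0,
    max_exons_filtered: int = 2,
) -> Tuple[List[TranscriptModel], List[TranscriptModel], Dict[str, EvidenceHit]]:
    """Drop 1-2 exon transcripts without sufficient evidence similarity.

    Transcripts with more than ``max_exons_filtered`` exons are always kept.
    A low-exon-count transcript is kept iff its best bit score against any
    evidence sequence is >= ``threshold_bits`` (kept at exactly the cutoff).
    Returns (kept, excluded, best-hit per scored query).
    """
    if not evidence_sequences:
        warnings.warn("empty evidence set: all 1-2 exon transcripts will be excluded")
    kept: List[TranscriptModel] = []
    excluded: List[TranscriptModel] = []
    hits: Dict[str, EvidenceHit] = {}
    for t in transcripts:
        if t.exon_count > max_exons_filtered:
            kept.append(t)
            continue
        query = transcript_sequences[t.transcript_id]
        best = EvidenceHit(t.transcript_id, None, 0, 0.0)
        for subject_id, subject in evidence_sequences.items():
            raw = local_align_score(query, subject, scheme)
            bits = bit_score(raw, scheme)
            if bits > best.bits:
                best = EvidenceHit(t.transcript_id, subject_id, raw, bits)
                if bits >= threshold_bits:
                    break  # decision made; best hit is provenance, not ranking
        hits[t.transcript_id] = best
        if best.bits >= threshold_bits:
            kept.append(t)
        else:
            excluded.append(t)
    return kept, excluded, hits
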