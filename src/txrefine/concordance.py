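"""Locus clustering, annotation overlap, and exact intron concordance.

Transcripts are grouped into gene loci by single-linkage exonic overlap on
the same strand; each transcript is scored for span overlap against each
annotation source (strand-agnostic, per the chr:start-stop rule) and each
intron for exact (chrom, start, end, strand) identity with annotated introns.
The summary mirrors the shape of the published Venn/locus figures.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .models import AnnotationSet, IntronKey, TranscriptModel, sorted_transcripts

#: Canonical source labels and their single-letter Venn codes.
SOURCE_LETTERS = {"Ensembl": "E", "RefSeq": "R", "OtherRefSeq": "O"}
VENN_REGIONS = ("E", "R", "O", "ER", "EO", "RO", "ERO", "none")


def venn_label(sources: Iterable[str]) -> str:
    letters = "".join(
        letter for src, letter in SOURCE_LETTERS.items() if src in set(sources)
    )
    return letters if letters else "none"


@dataclass
class GeneLocusCluster:
    """Single-linkage cluster of transcripts sharing exonic overlap."""

    locus_id: str
    chrom: str
    strand: str
    span: Tuple[int, int]
    member_ids: List[str]


class _UnionFind:
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


def _strands_compatible(a: str, b: str) -> bool:
    return a == b or a == "." or b == "."


def cluster_loci(
    transcripts: Sequence[TranscriptModel], by: str = "overlap"
) -> List[GeneLocusCluster]:
    """Group transcripts into gene loci.

    ``overlap`` (default): connected components under ">= 1 bp exonic overlap
    on the same chrom with compatible strands" ('.' overlaps both).
    ``gene_id``: trust pre-assigned gene_id grouping instead.
    Locus ids are deterministic, ordered by (chrom, span start).
    """
    txs = list(transcripts)
    if by == "gene_id":
        groups: Dict[str, List[TranscriptModel]] = {}
        for t in txs:
            groups.setdefault(t.gene_id or t.transcript_id, []).append(t)
        members = list(groups.values())
    elif by == "overlap":
        uf = _UnionFind(len(txs))
        trees: Dict[str, IntervalTree] = {}
        for i, t in enumerate(txs):
            tree = trees.setdefault(t.chrom, IntervalTree())
            for exon in t.exons:
                for hit in tree.overlap(exon.start, exon.end):
                    j = hit.data
                    if _strands_compatible(t.strand, txs[j].strand):
                        uf.union(i, j)
                tree.addi(exon.start, exon.end, i)
        comps: Dict[int, List[TranscriptModel]] = {}
        for i, t in enumerate(txs):
            comps.setdefault(uf.find(i), []).append(t)
        members = list(comps.values())
    else:
        raise ValueError(f"unknown clustering mode {by!r}")

    loci = []
    for group in members:
        group = sorted_transcripts(group)
        chrom = group[0].chrom
        span = (min(t.span_start for t in group), max(t.span_end for t in group))
        strands = {t.strand for t in group} - {"."}
        strand = strands.pop() if len(strands) == 1 else "."
        loci.append(
            GeneLocusCluster(
                locus_id="",
                chrom=chrom,
                strand=strand,
                span=span,
                member_ids=[t.transcript_id for t in group],
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.span[0], l.span[1]))
    for i, locus in enumerate(loci):
        locus.locus_id = f"locus_{i + 1:05d}"
    return loci


def overlap_gene_annotations(
    transcripts: Sequence[TranscriptModel],
    annotation_sets: Sequence[AnnotationSet],
) -> Dict[str, FrozenSet[str]]:
    """Per transcript, the annotation sources whose gene spans overlap its span.

    Overlap is >= 1 bp on the same chromosome; strand is ignored (the rule
    compares chr:start-stop positions only).
    """
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for ann in annotation_sets:
        for chrom, start, end, _gene in ann.gene_spans:
            trees.setdefault((ann.source_label, chrom), IntervalTree()).addi(start, end)
    out: Dict[str, FrozenSet[str]] = {}
    for t in transcripts:
        sources = set()
        for ann in annotation_sets:
            tree = trees.get((ann.source_label, t.chrom))
            if tree is not None and tree.overlap(t.span_start, t.span_end):
                sources.add(ann.source_label)
        out[t.transcript_id] = frozenset(sources)
    return out


def intron_concordance(
    transcript_introns: Sequence[IntronKey],
    annotation_sets: Sequence[AnnotationSet],
) -> List[FrozenSet[str]]:
    """Per intron, the sources containing an exactly identical intron.

    Exact means identical (chrom, start, end, strand); a '.'-strand intron on
    either side matches either strand.
    """
    by_source: Dict[str, set] = {}
    for ann in annotation_sets:
        by_source[ann.source_label] = {
            (k.chrom, k.start, k.end, k.strand) for k in ann.introns
        }
    out: List[FrozenSet[str]] = []
    for intron in transcript_introns:
        if intron.strand == ".":
            candidates = [
                (intron.chrom, intron.start, intron.end, s) for s in ("+", "-", ".")
            ]
        else:
            candidates = [
                (intron.chrom, intron.start, intron.end, intron.strand),
                (intron.chrom, intron.start, intron.end, "."),
            ]
        sources = {
            label
            for label, keys in by_source.items()
            if any(c in keys for c in candidates)
        }
        out.append(frozenset(sources))
    return out


@dataclass
class ConcordanceSummary:
    """Venn tallies, locus counts and the unannotated-transcript breakdown."""

    venn_transcripts: Dict[str, int] = field(default_factory=dict)
    venn_introns: Dict[str, int] = field(default_factory=dict)
    n_transcripts: int = 0
    n_introns: int = 0
    n_loci: int = 0
    loci_min2_exons: int = 0
    loci_min3_exons: int = 0
    transcripts_per_locus: Dict[int, int] = field(default_factory=dict)
    unannotated_total: int = 0
    unannotated_on_unplaced: int = 0
    unannotated_single_exon: int = 0

    def to_dict(self) -> Dict:
        d = {
            "venn_transcripts": dict(sorted(self.venn_transcripts.items())),
            "venn_introns": dict(sorted(self.venn_introns.items())),
            "n_transcripts": self.n_transcripts,
            "n_introns": self.n_introns,
            "n_loci": self.n_loci,
            "loci_min2_exons": self.loci_min2_exons,
            "loci_min3_exons": self.loci_min3_exons,
            "transcripts_per_locus": {
                str(k): v for k, v in sorted(self.transcripts_per_locus.items())
            },
            "unannotated_total": self.unannotated_total,
            "unannotated_on_unplaced": self.unannotated_on_unplaced,
            "unannotated_single_exon": self.unannotated_single_exon,
        }
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "ConcordanceSummary":
        return cls(
            venn_transcripts=dict(d["venn_transcripts"]),
            venn_introns=dict(d["venn_introns"]),
            n_transcripts=d["n_transcripts"],
            n_introns=d["n_introns"],
            n_loci=d["n_loci"],
            loci_min2_exons=d["loci_min2_exons"],
            loci_min3_exons=d["loci_min3_exons"],
            transcripts_per_locus={
                int(k): v for k, v in d["transcripts_per_locus"].items()
            },
            unannotated_total=d["unannotated_total"],
            unannotated_on_unplaced=d["unannotated_on_unplaced"],
            unannotated_single_exon=d["unannotated_single_exon"],
        )


def summarize_annotation(
    transcripts: Sequence[TranscriptModel],
    loci: Sequence[GeneLocusCluster],
    categories: Dict[str, FrozenSet[str]],
    intron_sets: Sequence[Tuple[IntronKey, FrozenSet[str]]],
    unplaced_pattern: str = "Un",
) -> ConcordanceSummary:
    """Tally Venn regions, locus exon-count classes, and the unannotated breakdown.

    ``intron_sets`` pairs each transcript intron with its concordant sources.
    Unplaced chromosomes are identified by a configurable name substring.
    Permutation-invariant in all inputs; region counts sum to the totals.
    """
    summary = ConcordanceSummary(
        venn_transcripts={r: 0 for r in VENN_REGIONS},
        venn_introns={r: 0 for r in VENN_REGIONS},
    )
    by_id = {t.transcript_id: t for t in transcripts}
    for t in transcripts:
        label = venn_label(categories.get(t.transcript_id, frozenset()))
        summary.venn_transcripts[label] += 1
        if label == "none":
            summary.unannotated_total += 1
            if unplaced_pattern in t.chrom:
                summary.unannotated_on_unplaced += 1
            if t.exon_count == 1:
                summary.unannotated_single_exon += 1
    for _intron, sources in intron_sets:
        summary.venn_introns[venn_label(sources)] += 1
    summary.n_transcripts = len(transcripts)
    summary.n_introns = len(intron_sets)
    summary.n_loci = len(loci)
    per_locus = Counter()
    for locus in loci:
        members = [by_id[m] for m in locus.member_ids]
        if any(m.exon_count >= 2 for m in members):
            summary.loci_min2_exons += 1
        if any(m.exon_count >= 3 for m in members):
            summary.loci_min3_exons += 1
        per_locus[len(members)] += 1
    summary.transcripts_per_locus = dict(sorted(per_locus.items()))
    return summary
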