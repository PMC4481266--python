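"""Locus clustering, gene-span overlap, intron concordance, and summaries."""

import pytest

from txrefine.concordance import (
    cluster_loci,
    intron_concordance,
    overlap_gene_annotations,
    summarize_annotation,
    venn_label,
)
from txrefine.models import AnnotationSet, ExonInterval, IntronKey, TranscriptModel


def tx(tid, spans, strand="+", chrom="chr1"):
    return TranscriptModel(
        tid, [ExonInterval(chrom, s, e, strand) for s, e in spans], strand
    )


def brute_force_components(transcripts):
    """Transitive closure over pairwise exonic overlap (the clustering oracle)."""
    def connected(a, b):
        if a.chrom != b.chrom:
            return False
        if not (a.strand == b.strand or "." in (a.strand, b.strand)):
            return False
        return any(
            ea.start < eb.end and eb.start < ea.end
            for ea in a.exons
            for eb in b.exons
        )

    groups = [{t.transcript_id} for t in transcripts]
    by_id = {t.transcript_id: t for t in transcripts}
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(
                    connected(by_id[a], by_id[b]) for a in groups[i] for b in groups[j]
                ):
                    groups[i] |= groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(g) for g in groups}


class TestClusterLoci:
    def test_disjoint_spans_two_loci(self):
        loci = cluster_loci([tx("a", [(0, 100)]), tx("b", [(500, 600)])])
        assert len(loci) == 2

    def test_transitive_chain_one_locus(self):
        a = tx("a", [(0, 100)])
        b = tx("b", [(50, 250)])
        c = tx("c", [(200, 300)])
        loci = cluster_loci([a, b, c])
        assert len(loci) == 1
        assert set(loci[0].member_ids) == {"a", "b", "c"}

    def test_intron_only_overlap_separate_loci(self):
        a = tx("a", [(0, 100), (900, 1000)])
        b = tx("b", [(400, 500)])  # inside a's intron
        assert len(cluster_loci([a, b])) == 2

    def test_opposite_strands_separate(self):
        loci = cluster_loci([tx("a", [(0, 100)], "+"), tx("b", [(0, 100)], "-")])
        assert len(loci) == 2

    def test_dot_strand_bridges(self):
        loci = cluster_loci([tx("a", [(0, 100)], "+"), tx("b", [(50, 150)], ".")])
        assert len(loci) == 1

    def test_gene_id_mode(self):
        a = tx("a", [(0, 100)])
        a.gene_id = "g1"
        b = tx("b", [(500, 600)])
        b.gene_id = "g1"
        assert len(cluster_loci([a, b], by="gene_id")) == 1

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(20):
            txs = []
            for i in range(int(rng.integers(5, 40))):
                start = int(rng.integers(0, 2000))
                n_ex = int(rng.integers(1, 4))
                spans = []
                pos = start
                for _ in range(n_ex):
                    length = int(rng.integers(20, 120))
                    spans.append((pos, pos + length))
                    pos += length + int(rng.integers(10, 100))
                strand = ["+", "-", "."][int(rng.integers(0, 3))]
                txs.append(tx(f"t{i}", spans, strand))
            got = {frozenset(l.member_ids) for l in cluster_loci(txs)}
            assert got == brute_force_components(txs)


class TestGeneOverlap:
    def _ann(self, label, spans):
        return AnnotationSet(label, gene_spans=[("chr1", s, e, f"g{s}") for s, e in spans])

    def test_one_bp_overlap_counts(self):
        sets = [self._ann("Ensembl", [(99, 200)])]
        out = overlap_gene_annotations([tx("t", [(0, 100)])], sets)
        assert out["t"] == frozenset({"Ensembl"})

    def test_no_overlap_empty(self):
        sets = [self._ann("Ensembl", [(500, 600)])]
        out = overlap_gene_annotations([tx("t", [(0, 100)])], sets)
        assert out["t"] == frozenset()

    def test_strand_ignored(self):
        sets = [self._ann("RefSeq", [(0, 100)])]
        out = overlap_gene_annotations([tx("t", [(0, 100)], "-")], sets)
        assert out["t"] == frozenset({"RefSeq"})

    def test_matches_brute_force(self, rng):
        spans = [(int(s), int(s) + int(l)) for s, l in zip(
            rng.integers(0, 5000, 500), rng.integers(10, 300, 500)
        )]
        half = len(spans) // 2
        sets = [
            self._ann("Ensembl", spans[:half]),
            self._ann("OtherRefSeq", spans[half:]),
        ]
        txs = [tx(f"t{i}", [(int(s), int(s) + int(l))]) for i, (s, l) in enumerate(
            zip(rng.integers(0, 5000, 200), rng.integers(10, 300, 200))
        )]
        got = overlap_gene_annotations(txs, sets)
        for t in txs:
            expected = set()
            for ann in sets:
                for _c, s, e, _g in ann.gene_spans:
                    if t.span_start < e and s < t.span_end:
                        expected.add(ann.source_label)
                        break
            assert got[t.transcript_id] == frozenset(expected)


class TestIntronConcordance:
    def _sets(self, introns):
        return [AnnotationSet("Ensembl", introns=set(introns))]

    def test_exact_match(self):
        key = IntronKey("chr1", 100, 200, "+")
        out = intron_concordance([key], self._sets([key]))
        assert out == [frozenset({"Ensembl"})]

    def test_one_bp_shift_no_match(self):
        out = intron_concordance(
            [IntronKey("chr1", 101, 200, "+")],
            self._sets([IntronKey("chr1", 100, 200, "+")]),
        )
        assert out == [frozenset()]

    def test_opposite_strand_no_match(self):
        out = intron_concordance(
            [IntronKey("chr1", 100, 200, "-")],
            self._sets([IntronKey("chr1", 100, 200, "+")]),
        )
        assert out == [frozenset()]

    def test_dot_strand_matches_either(self):
        out = intron_concordance(
            [IntronKey("chr1", 100, 200, ".")],
            self._sets([IntronKey("chr1", 100, 200, "-")]),
        )
        assert out == [frozenset({"Ensembl"})]

    def test_matches_brute_force(self, rng):
        ann = [
            IntronKey("chr1", int(s), int(s) + int(l), "+" if x < 0.5 else "-")
            for s, l, x in zip(
                rng.integers(0, 3000, 500), rng.integers(30, 200, 500), rng.random(500)
            )
        ]
        queries = [
            IntronKey("chr1", int(s), int(s) + int(l), ["+", "-", "."][int(k)])
            for s, l, k in zip(
                rng.integers(0, 3000, 200), rng.integers(30, 200, 200), rng.integers(0, 3, 200)
            )
        ]
        sets = self._sets(ann)
        got = intron_concordance(queries, sets)
        for q, sources in zip(queries, got):
            expected = any(
                a.chrom == q.chrom
                and a.start == q.start
                and a.end == q.end
                and (a.strand == q.strand or "." in (a.strand, q.strand))
                for a in ann
            )
            assert (len(sources) > 0) == expected


class TestSummarize:
    def test_empty_inputs_all_zero(self):
        summary = summarize_annotation([], [], {}, [])
        assert summary.n_transcripts == 0
        assert sum(summary.venn_transcripts.values()) == 0

    def test_all_single_exon_no_multiexon_loci(self):
        txs = [tx("a", [(0, 100)]), tx("b", [(500, 600)])]
        loci = cluster_loci(txs)
        summary = summarize_annotation(txs, loci, {t.transcript_id: frozenset() for t in txs}, [])
        assert summary.loci_min2_exons == 0

    def test_venn_tallies_conserve_totals(self, rng):
        txs = []
        cats = {}
        for i in range(50):
            start = int(rng.integers(0, 100_000))
            txs.append(tx(f"t{i}", [(start, start + 50)]))
            sources = [s for s in ("Ensembl", "RefSeq", "OtherRefSeq") if rng.random() < 0.4]
            cats[f"t{i}"] = frozenset(sources)
        loci = cluster_loci(txs)
        summary = summarize_annotation(txs, loci, cats, [])
        assert sum(summary.venn_transcripts.values()) == len(txs)
        assert sum(summary.transcripts_per_locus.values()) == summary.n_loci

    def test_unannotated_breakdown(self):
        txs = [
            tx("a", [(0, 100)], chrom="chrUn"),
            tx("b", [(0, 100), (200, 300)], chrom="chr1"),
        ]
        loci = cluster_loci(txs)
        cats = {"a": frozenset(), "b": frozenset()}
        summary = summarize_annotation(txs, loci, cats, [])
        assert summary.unannotated_total == 2
        assert summary.unannotated_on_unplaced == 1
        assert summary.unannotated_single_exon == 1

    def test_venn_labels(self):
        assert venn_label({"Ensembl"}) == "E"
        assert venn_label({"Ensembl", "OtherRefSeq"}) == "EO"
        assert venn_label(set()) == "none"
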