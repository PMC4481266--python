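"""Segment alignment, link candidates, spliced refinement, and merging."""

import pytest

from txrefine.linkmerge import (
    JunctionRecord,
    LinkCandidate,
    LinkRejection,
    MergeResult,
    align_segment,
    apply_merges,
    find_link_candidates,
    junction_dinucleotides,
    merge_by_noncanonical_junction,
    refine_link,
)
from txrefine.models import ExonInterval, IntronKey, TranscriptModel, revcomp
from txrefine.orf import build_transcript_sequence


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestAlignSegment:
    def test_unique_exact_hit(self, rng):
        seqs = {"t1": random_seq(rng, 200)}
        segment = seqs["t1"][10:35]
        aln = align_segment(segment, "s", seqs)
        assert len(aln.hits) == 1
        hit = aln.hits[0]
        assert (hit.target_transcript_id, hit.offset, hit.mismatches) == ("t1", 10, 0)

    def test_one_mismatch_found(self, rng):
        seqs = {"t1": random_seq(rng, 200)}
        segment = list(seqs["t1"][50:75])
        segment[12] = "A" if segment[12] != "A" else "C"
        aln = align_segment("".join(segment), "s", seqs)
        assert any(h.offset == 50 and h.mismatches == 1 for h in aln.hits)

    def test_two_mismatches_not_found(self, rng):
        seqs = {"t1": random_seq(rng, 200)}
        segment = list(seqs["t1"][50:75])
        for i in (3, 12):
            segment[i] = "A" if segment[i] != "A" else "C"
        aln = align_segment("".join(segment), "s", seqs)
        assert not any(h.offset == 50 for h in aln.hits)

    def test_reverse_complement_hit(self, rng):
        seqs = {"t1": random_seq(rng, 200)}
        aln = align_segment(revcomp(seqs["t1"][10:35]), "s", seqs)
        assert any(h.strand == "-" and h.offset == 10 for h in aln.hits)

    def test_no_hit_anywhere(self, rng):
        seqs = {"t1": "A" * 200}
        aln = align_segment("C" * 25, "s", seqs)
        assert aln.hits == [] and not aln.multimapped

    def test_multimapped_suppressed(self, rng):
        core = random_seq(rng, 25)
        seqs = {f"t{i}": random_seq(rng, 30) + core + random_seq(rng, 30) for i in range(4)}
        aln = align_segment(core, "s", seqs)
        assert aln.hits == [] and aln.multimapped

    def test_three_hits_kept(self, rng):
        core = random_seq(rng, 25)
        seqs = {f"t{i}": random_seq(rng, 30) + core + random_seq(rng, 30) for i in range(3)}
        aln = align_segment(core, "s", seqs)
        assert len(aln.hits) == 3 and not aln.multimapped

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            align_segment("ACGT", "s", {"t": "ACGT" * 20})


def _linked_pair(rng, gap=45_000, strand="+", chrom="chr1"):
    a = TranscriptModel("A", [ExonInterval(chrom, 1000, 5000, strand)], strand)
    b = TranscriptModel(
        "B", [ExonInterval(chrom, 5000 + gap, 6000 + gap, strand)], strand
    )
    return {"A": a, "B": b}


def _alignments(read_id, tid5, tid3, strand="+"):
    from txrefine.linkmerge import SegmentAlignment, SegmentHit

    h5 = SegmentHit(read_id + "/5p", tid5, 10, strand, 0)
    h3 = SegmentHit(read_id + "/3p", tid3, 5, strand, 0)
    return {read_id: (
        SegmentAlignment(read_id + "/5p", [h5]),
        SegmentAlignment(read_id + "/3p", [h3]),
    )}


class TestLinkCandidates:
    def test_proper_link_emitted_with_gap(self, rng):
        txs = _linked_pair(rng)
        (cand,) = find_link_candidates(_alignments("r", "A", "B"), txs)
        assert (cand.transcript_a_id, cand.transcript_b_id) == ("A", "B")
        assert cand.genomic_gap == 45_000

    def test_distance_window_boundary(self, rng):
        for gap, expected in ((200_000, 1), (200_001, 0)):
            txs = _linked_pair(rng, gap=gap)
            cands = find_link_candidates(_alignments("r", "A", "B"), txs)
            assert len(cands) == expected

    def test_opposite_transcript_strands_rejected(self, rng):
        txs = _linked_pair(rng)
        txs["B"] = TranscriptModel("B", [ExonInterval("chr1", 50_000, 51_000, "-")], "-")
        assert find_link_candidates(_alignments("r", "A", "B"), txs) == []

    def test_mixed_segment_orientations_rejected(self, rng):
        from txrefine.linkmerge import SegmentAlignment, SegmentHit

        txs = _linked_pair(rng)
        alns = {
            "r": (
                SegmentAlignment("r/5p", [SegmentHit("r/5p", "A", 10, "+", 0)]),
                SegmentAlignment("r/3p", [SegmentHit("r/3p", "B", 5, "-", 0)]),
            )
        }
        assert find_link_candidates(alns, txs) == []

    def test_wrong_order_rejected(self, rng):
        # forward-oriented segments with the 5' end in the downstream transcript
        txs = _linked_pair(rng)
        assert find_link_candidates(_alignments("r", "B", "A"), txs) == []

    def test_minus_strand_proper_orientation(self, rng):
        txs = _linked_pair(rng, strand="-")
        # for a minus-strand pair the 5' segment lands in the genomically
        # right transcript
        (cand,) = find_link_candidates(_alignments("r", "B", "A"), txs)
        assert (cand.transcript_a_id, cand.transcript_b_id) == ("A", "B")


class TestRefineLink:
    def _setup(self, rng, tolerance_offset=0):
        genome = {"chr1": random_seq(rng, 4000)}
        a = TranscriptModel("A", [ExonInterval("chr1", 100, 400, "+")], "+")
        b = TranscriptModel("B", [ExonInterval("chr1", 900, 1300, "+")], "+")
        txs = {"A": a, "B": b}
        tss = {k: build_transcript_sequence(t, genome) for k, t in txs.items()}
        read = tss["A"].sequence[-40:] + tss["B"].sequence[:40]
        cand = LinkCandidate("r", "A", "B", 500)
        intron = IntronKey("chr1", 400 + tolerance_offset, 900 + tolerance_offset, "+")
        return genome, txs, tss, read, cand, [intron]

    def test_exact_annotated_intron_accepted(self, rng):
        genome, txs, tss, read, cand, introns = self._setup(rng)
        result = refine_link(read, genome, cand, tss, txs, introns)
        assert isinstance(result, MergeResult)
        assert result.linking_intron == IntronKey("chr1", 400, 900, "+")

    def test_tolerance_boundary(self, rng):
        genome, txs, tss, read, cand, introns = self._setup(rng, tolerance_offset=10)
        assert isinstance(refine_link(read, genome, cand, tss, txs, introns), MergeResult)
        genome, txs, tss, read, cand, introns = self._setup(rng, tolerance_offset=11)
        result = refine_link(read, genome, cand, tss, txs, introns)
        assert isinstance(result, LinkRejection)
        assert result.reason == "intron_not_annotated"

    def test_unalignable_read_rejected(self, rng):
        genome, txs, tss, _read, cand, introns = self._setup(rng)
        result = refine_link("T" * 80, genome, cand, tss, txs, introns, max_total_mismatches=3)
        assert isinstance(result, LinkRejection)
        assert result.reason == "no_spliced_alignment"


class TestJunctionMerge:
    def _pair(self):
        a = TranscriptModel("A", [ExonInterval("chr1", 100, 400, "+")], "+")
        b = TranscriptModel("B", [ExonInterval("chr1", 900, 1300, "+")], "+")
        return [a, b]

    def test_noncanonical_junction_merges(self):
        j = JunctionRecord("chr1", 400, 900, "+", "GC-AG")
        results, log = merge_by_noncanonical_junction(self._pair(), [j])
        assert len(results) == 1 and log == []
        assert results[0].mechanism == "noncanonical_junction"

    def test_canonical_junction_ignored(self):
        j = JunctionRecord("chr1", 400, 900, "+", "GT-AG")
        results, _ = merge_by_noncanonical_junction(self._pair(), [j])
        assert results == []

    def test_interior_donor_no_merge(self):
        j = JunctionRecord("chr1", 300, 900, "+", "GC-AG")
        results, _ = merge_by_noncanonical_junction(self._pair(), [j])
        assert results == []

    def test_ambiguous_attachment_logged(self):
        txs = self._pair() + [
            TranscriptModel("C", [ExonInterval("chr1", 200, 400, "+")], "+")
        ]
        j = JunctionRecord("chr1", 400, 900, "+", "GC-AG")
        results, log = merge_by_noncanonical_junction(txs, [j])
        assert results == [] and len(log) == 1

    def test_dinucleotide_extraction(self):
        genome = {"c": "AAAGTCCCCAGAAA"}
        assert junction_dinucleotides(genome, "c", 3, 11, "+") == "GT-AG"
        assert junction_dinucleotides(genome, "c", 3, 11, "-") == "CT-AC"


class TestApplyMerges:
    def _tx(self, tid, start, end):
        return TranscriptModel(tid, [ExonInterval("chr1", start, end, "+")], "+")

    def _merge(self, a, b):
        return MergeResult(a, b, IntronKey("chr1", 1, 2, "+"))

    def test_connected_components_transitive(self):
        txs = [self._tx("A", 0, 100), self._tx("B", 200, 300), self._tx("C", 400, 500)]
        merged, prov = apply_merges(txs, [self._merge("A", "B"), self._merge("B", "C")])
        assert len(merged) == 1
        assert prov[merged[0].transcript_id] == ["A", "B", "C"]

    def test_no_exonic_bases_lost(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 10))
            txs = []
            pos = 0
            for i in range(n):
                start = pos + int(rng.integers(10, 50))
                end = start + int(rng.integers(20, 80))
                txs.append(self._tx(f"t{i}", start, end))
                pos = end
            edges = [
                self._merge(f"t{int(i)}", f"t{int(j)}")
                for i, j in zip(rng.integers(0, n, 3), rng.integers(0, n, 3))
                if i != j
            ]
            merged, _ = apply_merges(txs, edges)
            before = {p for t in txs for e in t.exons for p in range(e.start, e.end)}
            after = {p for t in merged for e in t.exons for p in range(e.start, e.end)}
            assert before <= after

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 20))
            txs = [self._tx(f"t{i}", 1000 * i, 1000 * i + 100) for i in range(n)]
            pairs = set()
            for _ in range(int(rng.integers(0, n))):
                i, j = int(rng.integers(0, n)), int(rng.integers(0, n))
                if i != j:
                    pairs.add((f"t{min(i, j)}", f"t{max(i, j)}"))
            merged, prov = apply_merges(txs, [self._merge(a, b) for a, b in pairs])
            # oracle: transitive closure over the pair list
            comp = {f"t{i}": {f"t{i}"} for i in range(n)}
            changed = True
            while changed:
                changed = False
                for a, b in pairs:
                    if comp[a] is not comp[b]:
                        union = comp[a] | comp[b]
                        for m in union:
                            comp[m] = union
                        changed = True
            expected = {frozenset(c) for c in comp.values()}
            got = set()
            for t in merged:
                got.add(frozenset(prov.get(t.transcript_id, [t.transcript_id])))
            assert got == expected
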