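"""Transcript sequence construction, ORF scanning, and effect classification."""

import pytest

from txrefine.models import ExonInterval, IntronKey, TranscriptModel, VariantRecord, revcomp
from txrefine.orf import (
    VariantApplicationSkip,
    apply_variant_to_transcript,
    build_transcript_sequence,
    classify_error_mechanism,
    classify_orf_effect,
    longest_orf,
    map_genomic_to_transcript,
)

STOPS = ("TAA", "TAG", "TGA")


def orf_oracle(sequence, scan_both_strands=True):
    """Brute-force enumeration over every (ATG, first in-frame stop) pair in
    all frames of both strands; returns (length, strand, start) or None."""
    best = None
    strands = [("forward", sequence)]
    if scan_both_strands:
        strands.append(("reverse", revcomp(sequence)))
    for strand, s in strands:
        for i in range(len(s) - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i + 3
            while j <= len(s) - 3:
                if s[j : j + 3] in STOPS:
                    cand = (j + 3 - i, strand, i)
                    if best is None or _better(cand, best):
                        best = cand
                    break
                j += 3
    return best


def _better(cand, best):
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[1] != best[1]:
        return cand[1] == "forward"
    return cand[2] < best[2]


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestTranscriptSequence:
    genome = {"c": "ACGTTTGCA"}

    def test_splice_out_plus_strand(self):
        t = TranscriptModel(
            "t", [ExonInterval("c", 0, 3, "+"), ExonInterval("c", 6, 9, "+")], "+"
        )
        assert build_transcript_sequence(t, self.genome).sequence == "ACGGCA"

    def test_minus_strand_reverse_complement(self):
        t = TranscriptModel(
            "t", [ExonInterval("c", 0, 3, "-"), ExonInterval("c", 6, 9, "-")], "-"
        )
        assert build_transcript_sequence(t, self.genome).sequence == "TGCCGT"

    def test_out_of_bounds_exon(self):
        t = TranscriptModel("t", [ExonInterval("c", 5, 20, "+")], "+")
        with pytest.raises(ValueError):
            build_transcript_sequence(t, self.genome)

    def test_map_first_exonic_base(self):
        t = TranscriptModel(
            "t", [ExonInterval("c", 0, 3, "+"), ExonInterval("c", 6, 9, "+")], "+"
        )
        ts = build_transcript_sequence(t, self.genome)
        assert map_genomic_to_transcript(ts, 0) == 0
        assert map_genomic_to_transcript(ts, 4) is None  # intronic

    def test_map_bijection_both_strands(self, rng):
        genome = {"g": random_seq(rng, 3000)}
        for strand in ("+", "-"):
            exons = [
                ExonInterval("g", 100, 400, strand),
                ExonInterval("g", 700, 900, strand),
                ExonInterval("g", 1500, 1600, strand),
            ]
            ts = build_transcript_sequence(TranscriptModel("t", exons, strand), genome)
            # brute-force position enumeration
            exonic = [p for e in exons for p in range(e.start, e.end)]
            if strand == "-":
                exonic = exonic[::-1]
            for offset, gpos in enumerate(exonic):
                assert ts.genomic_positions[offset] == gpos
                assert map_genomic_to_transcript(ts, gpos) == offset
            for gpos in (0, 500, 1000, 2500):
                assert map_genomic_to_transcript(ts, gpos) is None


class TestApplyVariant:
    def _setup(self, rng, strand="+"):
        genome = {"g": random_seq(rng, 500)}
        exons = [ExonInterval("g", 50, 150, strand), ExonInterval("g", 250, 350, strand)]
        t = TranscriptModel("t", exons, strand)
        return genome, build_transcript_sequence(t, genome)

    def test_snp_preserves_length(self, rng):
        genome, ts = self._setup(rng)
        ref = genome["g"][100]
        alt = "A" if ref != "A" else "C"
        v = VariantRecord("g", 101, ref, [alt])
        out = apply_variant_to_transcript(ts, v)
        assert len(out) == len(ts.sequence)
        assert out[50] == alt

    def test_deletion_shortens_by_one(self, rng):
        genome, ts = self._setup(rng)
        v = VariantRecord("g", 101, genome["g"][100:102], [genome["g"][100]])
        out = apply_variant_to_transcript(ts, v)
        assert len(out) == len(ts.sequence) - 1

    def test_insertion_then_inverse_deletion_round_trip(self, rng):
        genome, ts = self._setup(rng)
        anchor = genome["g"][100]
        ins = VariantRecord("g", 101, anchor, [anchor + "GTC"])
        inserted = apply_variant_to_transcript(ts, ins)
        assert len(inserted) == len(ts.sequence) + 3
        assert inserted[:51] + inserted[54:] == ts.sequence

    def test_minus_strand_applies_reverse_complement(self, rng):
        genome, ts = self._setup(rng, strand="-")
        ref = genome["g"][100]
        alt = "A" if ref != "A" else "C"
        v = VariantRecord("g", 101, ref, [alt])
        out = apply_variant_to_transcript(ts, v)
        offset = map_genomic_to_transcript(ts, 100)
        assert out[offset] == revcomp(alt)

    def test_intronic_variant_skipped(self, rng):
        genome, ts = self._setup(rng)
        v = VariantRecord("g", 201, genome["g"][200], ["A" if genome["g"][200] != "A" else "C"])
        with pytest.raises(VariantApplicationSkip, match="not_exonic"):
            apply_variant_to_transcript(ts, v)

    def test_boundary_overlap_skipped(self, rng):
        genome, ts = self._setup(rng)
        # deletion starting in the exon and running into the intron
        v = VariantRecord("g", 149, genome["g"][148:153], [genome["g"][148]])
        with pytest.raises(VariantApplicationSkip, match="boundary_overlap"):
            apply_variant_to_transcript(ts, v)

    def test_length_change_matches_allele_lengths(self, rng):
        genome, ts = self._setup(rng)
        for ref_len, alt_len in ((1, 1), (1, 4), (3, 1)):
            ref = genome["g"][100 : 100 + ref_len]
            alt = ref[0] + "G" * (alt_len - 1) if alt_len > 1 else ("A" if ref[0] != "A" else "C")
            if len(ref) == len(alt) == 1 and ref == alt:
                continue
            v = VariantRecord("g", 101, ref, [alt])
            out = apply_variant_to_transcript(ts, v)
            assert abs(len(out) - len(ts.sequence)) == abs(len(alt) - len(ref))


class TestLongestOrf:
    def test_single_complete_orf(self):
        orf = longest_orf("ATGAAATAG", scan_both_strands=False)
        assert orf.length == 9 and orf.start == 0

    def test_no_atg_returns_none(self):
        assert longest_orf("CCCCCCCCC") is None

    def test_truncated_orf_not_counted(self):
        assert longest_orf("ATGAAAAAA", scan_both_strands=False) is None

    def test_reverse_strand_found(self):
        seq = revcomp("ATGAAATAG")
        orf = longest_orf(seq)
        assert orf.length == 9 and orf.strand == "reverse"

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            seq = random_seq(rng, int(rng.integers(30, 400)))
            got = longest_orf(seq)
            expected = orf_oracle(seq)
            if expected is None:
                assert got is None
            else:
                assert (got.length, got.strand, got.start) == expected

    def test_invariant_under_noncoding_suffix(self):
        seq = "ATGAAACCCTAG"
        extended = seq + "CCCCCC"  # no ATG, no in-frame stop extension
        assert longest_orf(extended).length == longest_orf(seq).length


class TestOrfEffect:
    def test_frameshift_repairing_deletion_extends(self):
        # reference carries an extra C inside a homopolymer: its ORF stops
        # early; removing the C fuses the two halves
        truth = "ATG" + "GAT" + "CCC" + "CAT" + "GAA" * 10 + "TAA"
        ref_seq = truth[:6] + "C" + truth[6:]
        genome = {"g": "TTTTT" + ref_seq + "TTTTT"}
        t = TranscriptModel("t", [ExonInterval("g", 5, 5 + len(ref_seq), "+")], "+")
        ts = build_transcript_sequence(t, genome)
        v = VariantRecord("g", 11, genome["g"][10:12], [genome["g"][10]])
        eff = classify_orf_effect(ts, v, genome=genome)
        assert eff.effect == "extending"
        assert eff.longest_orf_alt == len(truth)

    def test_downstream_snp_neutral(self):
        seq = "ATGAAATAGCCCCCC"
        genome = {"g": seq}
        t = TranscriptModel("t", [ExonInterval("g", 0, len(seq), "+")], "+")
        ts = build_transcript_sequence(t, genome)
        v = VariantRecord("g", 12, "C", ["G"])
        assert classify_orf_effect(ts, v, genome=genome).effect == "neutral"

    def test_premature_stop_deletion_shortens(self):
        # deleting one base inside the ORF frameshifts into a stop
        seq = "ATGAAAGGGTAACCCTAG"
        genome = {"g": seq}
        t = TranscriptModel("t", [ExonInterval("g", 0, len(seq), "+")], "+")
        ts = build_transcript_sequence(t, genome)
        v = VariantRecord("g", 4, seq[3:5], [seq[3]])
        eff = classify_orf_effect(ts, v, genome=genome)
        assert eff.longest_orf_alt < eff.longest_orf_ref
        assert eff.effect == "shortening"


class TestErrorMechanism:
    def test_homopolymer_deletion_flagged(self):
        genome = {"g": "TACCGTT"}
        v = VariantRecord("g", 2, "AC", ["A"])  # deletes one C next to a C
        slip, mimic = classify_error_mechanism(v, genome, [])
        assert slip and not mimic

    def test_non_homopolymer_deletion_not_flagged(self):
        genome = {"g": "TACGGTT"}
        v = VariantRecord("g", 2, "AC", ["A"])  # C flanked by A and G
        slip, _ = classify_error_mechanism(v, genome, [])
        assert not slip

    def test_homopolymer_insertion_flagged(self):
        genome = {"g": "TACCGTT"}
        v = VariantRecord("g", 2, "A", ["AC"])
        slip, _ = classify_error_mechanism(v, genome, [])
        assert slip

    def test_snp_not_applicable(self):
        genome = {"g": "TACG"}
        v = VariantRecord("g", 2, "A", ["G"])
        assert classify_error_mechanism(v, genome, []) == (False, False)

    def test_intron_mimic_size_and_distance(self, rng):
        seq = random_seq(rng, 300)
        genome = {"g": seq}
        # 85 bp deletion at 0-based 100; annotated 85 bp intron starting 4 bp away
        v = VariantRecord("g", 100, seq[99 : 99 + 86], [seq[99]])
        near = [IntronKey("g", 104, 104 + 85, "+")]
        far = [IntronKey("g", 111, 111 + 85, "+")]
        wrong_size = [IntronKey("g", 104, 104 + 84, "+")]
        assert classify_error_mechanism(v, genome, near)[1] is True
        assert classify_error_mechanism(v, genome, far)[1] is False
        assert classify_error_mechanism(v, genome, wrong_size)[1] is False
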