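"""Core data model, coordinate conventions, and format round-trips."""

import numpy as np
import pytest

from txrefine.io import (
    ParseError,
    parse_bed12,
    parse_fasta,
    parse_gtf,
    parse_vcf,
    write_gtf,
    write_vcf,
    bed12_line,
)
from txrefine.models import (
    ExonInterval,
    IntronKey,
    TranscriptModel,
    ValidationError,
    VariantRecord,
    introns_of,
)


def _random_transcript(rng, tid, chrom="chr1"):
    k = int(rng.integers(1, 6))
    exons = []
    pos = int(rng.integers(0, 1000))
    strand = ["+", "-", "."][int(rng.integers(0, 3))]
    for _ in range(k):
        length = int(rng.integers(20, 200))
        exons.append(ExonInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(30, 300))
    return TranscriptModel(transcript_id=tid, exons=exons, strand=strand, gene_id=f"g_{tid}")


class TestGtf:
    def test_coordinate_convention_shift(self):
        gtf = (
            'chr1\tx\texon\t100\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        (t,) = parse_gtf(gtf)
        assert [(e.start, e.end) for e in t.exons] == [(99, 200), (300, 400)]
        assert t.strand == "+"

    def test_empty_stream(self):
        assert parse_gtf("") == []

    def test_single_exon_serialization(self):
        t = TranscriptModel("t1", [ExonInterval("c1", 0, 10, "+")], "+")
        line = write_gtf([t]).splitlines()[0].split("\t")
        assert (line[3], line[4]) == ("1", "10")

    def test_round_trip_random_transcripts(self, rng):
        transcripts = [_random_transcript(rng, f"t{i}") for i in range(50)]
        reparsed = parse_gtf(write_gtf(transcripts))
        by_id = {t.transcript_id: t for t in reparsed}
        for t in transcripts:
            other = by_id[t.transcript_id]
            assert [(e.start, e.end) for e in other.exons] == [
                (e.start, e.end) for e in t.exons
            ]
            assert other.strand == t.strand and other.gene_id == t.gene_id

    def test_deterministic_output(self, rng):
        transcripts = [_random_transcript(rng, f"t{i}") for i in range(10)]
        assert write_gtf(transcripts) == write_gtf(transcripts)

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(ParseError, match="line 1"):
            parse_gtf("chr1\tonly\tthree\n")

    def test_unknown_attributes_preserved(self):
        gtf = 'chr1\tx\texon\t1\t50\t.\t+\t.\tgene_id "g"; transcript_id "t"; FPKM "3.5";\n'
        out = write_gtf(parse_gtf(gtf))
        assert 'FPKM "3.5";' in out


class TestVcf:
    def test_homopolymer_deletion_record(self):
        # the published example site: CC > C, hom-alt, AD 0,23
        vcf = "chr1\t42863989\t.\tCC\tC\t.\tPASS\tQD=20\tGT:AD\t1/1:0,23\n"
        (rec,) = parse_vcf(vcf)
        assert rec.variant_class == "deletion"
        assert rec.genotype == (1, 1)
        assert rec.allele_depths == [0, 23]
        assert rec.info_metrics["QD"] == 20.0

    def test_missing_metric_left_absent(self):
        (rec,) = parse_vcf("chr1\t5\t.\tA\tG\t.\t.\tMQ=50\tGT\t0/1\n")
        assert "QD" not in rec.info_metrics

    def test_missing_gt_flags_record(self):
        (rec,) = parse_vcf("chr1\t5\t.\tA\tG\t.\t.\t.\tGT\t./.\n")
        assert rec.genotype is None

    def test_multiallelic_kept_as_one_record(self):
        (rec,) = parse_vcf("chr1\t5\t.\tA\tG,T\t.\t.\t.\tGT\t1/2\n")
        assert rec.alt_alleles == ["G", "T"]

    def test_round_trip_random_records(self, rng):
        records = []
        for i in range(100):
            pos = int(rng.integers(1, 10_000))
            kind = int(rng.integers(0, 3))
            if kind == 0:
                ref, alt = "A", "G"
            elif kind == 1:
                ref, alt = "A", "AC"
            else:
                ref, alt = "AC", "A"
            gt = [(0, 1), (1, 1), None][int(rng.integers(0, 3))]
            records.append(
                VariantRecord(
                    chrom="chr1",
                    pos=pos,
                    ref_allele=ref,
                    alt_alleles=[alt],
                    genotype=gt,
                    allele_depths=[int(rng.integers(0, 40)), int(rng.integers(0, 40))],
                    info_metrics={"QD": float(round(rng.uniform(0, 30), 2))},
                )
            )
        reparsed = parse_vcf(write_vcf(records))
        for a, b in zip(records, reparsed):
            assert (a.chrom, a.pos, a.ref_allele, a.alt_alleles) == (
                b.chrom,
                b.pos,
                b.ref_allele,
                b.alt_alleles,
            )
            assert a.genotype == b.genotype and a.allele_depths == b.allele_depths

    def test_malformed_allele_rejected(self):
        with pytest.raises(ParseError):
            parse_vcf("chr1\t5\t.\tAX\tG\t.\t.\t.\tGT\t0/1\n")


class TestFasta:
    def test_lowercase_uppercased(self):
        assert parse_fasta(">c1\nacgt\n") == {"c1": "ACGT"}

    def test_two_records_order_preserved(self):
        genome = parse_fasta(">a\nAC\n>b\nGT\n")
        assert list(genome) == ["a", "b"]

    def test_invalid_base_rejected(self):
        with pytest.raises(ValidationError):
            parse_fasta(">c1\nACGR\n")

    def test_duplicate_name_rejected(self):
        with pytest.raises(ValidationError):
            parse_fasta(">c1\nAC\n>c1\nGT\n")


class TestBed12AndIntrons:
    def test_block_gap_arithmetic(self):
        line = "chr1\t1000\t1400\tg1\t0\t+\t1000\t1400\t0\t2\t100,100,\t0,300,\n"
        ann = parse_bed12(line, "Ensembl")
        assert ann.introns == {IntronKey("chr1", 1100, 1300, "+")}
        assert ann.gene_spans == [("chr1", 1000, 1400, "g1")]

    def test_single_block_no_introns(self):
        line = "chr1\t10\t60\tg1\t0\t-\t10\t60\t0\t1\t50,\t0,\n"
        assert parse_bed12(line, "RefSeq").introns == set()

    def test_inconsistent_block_count(self):
        line = "chr1\t10\t60\tg1\t0\t-\t10\t60\t0\t2\t50,\t0,\n"
        with pytest.raises(ParseError):
            parse_bed12(line, "RefSeq")

    def test_bed12_introns_match_gtf_introns(self, rng):
        for i in range(50):
            t = _random_transcript(rng, f"t{i}")
            ann = parse_bed12(bed12_line(t), "Ensembl")
            assert ann.introns == set(introns_of(t))

    def test_introns_of_gaps(self):
        t = TranscriptModel(
            "t",
            [
                ExonInterval("c", 100, 200, "+"),
                ExonInterval("c", 300, 400, "+"),
                ExonInterval("c", 500, 600, "+"),
            ],
            "+",
        )
        assert introns_of(t) == [
            IntronKey("c", 200, 300, "+"),
            IntronKey("c", 400, 500, "+"),
        ]

    def test_single_exon_no_introns(self):
        t = TranscriptModel("t", [ExonInterval("c", 0, 10, "+")], "+")
        assert introns_of(t) == []

    def test_length_conservation(self, rng):
        for i in range(50):
            t = _random_transcript(rng, f"t{i}")
            total = sum(e.length for e in t.exons) + sum(i.length for i in t.introns())
            assert total == t.span_end - t.span_start

    def test_introns_disjoint_from_exons(self, rng):
        for i in range(30):
            t = _random_transcript(rng, f"t{i}")
            exonic = {p for e in t.exons for p in range(e.start, e.end)}
            intronic = {p for k in t.introns() for p in range(k.start, k.end)}
            assert not (exonic & intronic)


class TestModelInvariants:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValidationError):
            TranscriptModel(
                "t",
                [ExonInterval("c", 0, 100, "+"), ExonInterval("c", 50, 150, "+")],
                "+",
            )

    def test_zero_length_intron_rejected(self):
        with pytest.raises(ValidationError):
            TranscriptModel(
                "t",
                [ExonInterval("c", 0, 100, "+"), ExonInterval("c", 100, 150, "+")],
                "+",
            )

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValidationError):
            TranscriptModel(
                "t",
                [ExonInterval("c1", 0, 10, "+"), ExonInterval("c2", 20, 30, "+")],
                "+",
            )

    def test_variant_class_derivation(self):
        assert VariantRecord("c", 5, "A", ["G"]).variant_class == "snp"
        assert VariantRecord("c", 5, "A", ["AC"]).variant_class == "insertion"
        assert VariantRecord("c", 5, "AC", ["A"]).variant_class == "deletion"
        assert VariantRecord("c", 5, "A", ["G", "AC"]).variant_class == "mixed"
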