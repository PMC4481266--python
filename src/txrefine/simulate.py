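"""Deterministic synthetic-data generator with planted ground truth.

Emulates, at desk scale, the data shapes the pipeline consumes: a small
reference genome carrying multi-exon genes, fragmented transcript
assemblies with long reads guaranteed to link the fragments, three
partially overlapping annotation sources, and RNA/genomic/comparison
variant-call sets in which "reference errors" are planted by construction:
the reference copy of a host gene's coding sequence is disrupted (an extra
or missing homopolymer base, a premature-stop SNP, or an inserted
intron-sized segment), the RNA-side variant corrects it, and genomic
resequencing of the reference individual shows it as homozygous.

Every stage is seeded; a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import io as txio
from .linkmerge import JunctionRecord, junction_dinucleotides
from .models import (
    AlignmentRecord,
    AnnotationSet,
    ExonInterval,
    GenomeSequence,
    IntronKey,
    ReadRecord,
    TranscriptModel,
    revcomp,
)
from .orf import build_transcript_sequence, longest_orf
from .variants import VariantRecord, normalize_allele

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")
NONSTOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOPS
)
#: Codons that are stop-free in frame 0 but contain stop codons at both
#: shifted phases; placed downstream of planted frameshifts so the
#: reference copy's ORF terminates promptly.
FRAMESHIFT_GUARD = ("CTA", "ATA", "ACT", "AAC")

NONCANONICAL_SITES = (("GC", "AG"), ("CT", "AC"), ("AT", "AC"))

VENN_REGIONS_PROBS = {
    frozenset({"Ensembl", "RefSeq", "OtherRefSeq"}): 0.28,
    frozenset({"Ensembl", "RefSeq"}): 0.08,
    frozenset({"Ensembl", "OtherRefSeq"}): 0.16,
    frozenset({"RefSeq", "OtherRefSeq"}): 0.05,
    frozenset({"Ensembl"}): 0.15,
    frozenset({"RefSeq"}): 0.05,
    frozenset({"OtherRefSeq"}): 0.11,
    frozenset(): 0.12,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset (all stages seeded)."""

    seed: int
    chrom_names: Tuple[str, ...] = ("chr1", "chrUn")
    chrom_length: int = 100_000
    n_genes: int = 30
    exon_count_range: Tuple[int, int] = (2, 7)
    exon_length_range: Tuple[int, int] = (120, 400)
    intron_length_range: Tuple[int, int] = (70, 400)
    fraction_noncanonical_introns: float = 0.1
    n_fragmented_transcripts: int = 8
    n_linking_reads: int = 2
    n_decoy_reads: int = 6
    read_error_rate: float = 0.005
    n_planted_snp_errors: int = 3
    n_planted_ins_errors: int = 3
    n_planted_del_errors: int = 4  # the last one is the intron-mimicking deletion
    mimic_deletion_length: int = 30
    n_het_decoys: int = 3  # one snp, one insertion, one deletion
    n_unsupported_decoys: int = 3
    n_neutral_variants: int = 12
    n_failing_records: int = 8
    n_comparison_datasets: int = 5
    fraction_of_errors_shared: float = 0.6
    known_fraction: float = 0.3
    n_noise_transcripts: int = 6
    n_single_exon_genes: int = 2
    n_two_exon_genes: int = 1

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in (
            "n_genes",
            "n_fragmented_transcripts",
            "n_comparison_datasets",
            "n_noise_transcripts",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fraction_noncanonical_introns", "fraction_of_errors_shared", "known_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PlantedVariant:
    """Ground truth for one emitted RNA variant allele."""

    record_id: str
    key: Tuple[str, int, str, str]  # normalized (chrom, pos, ref, alt)
    variant_class: str  # snp / insertion / deletion
    group: str  # planted_error / het_decoy / unsupported_decoy / neutral
    host_transcript_id: str
    homopolymer_slip: bool = False
    intron_mimic: bool = False


@dataclass
class TruthSet:
    """Everything the generator knows, for planted-truth acceptance tests."""

    true_transcripts: List[TranscriptModel] = field(default_factory=list)
    fragment_parents: Dict[str, str] = field(default_factory=dict)
    true_links: List[Tuple[str, str, str]] = field(default_factory=list)  # parent, fragA, fragB
    planted: List[PlantedVariant] = field(default_factory=list)
    gene_membership: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    expected_filter_fail: Dict[str, List[str]] = field(default_factory=dict)
    expected_genomic_filter_fail: Dict[str, List[str]] = field(default_factory=dict)
    expected_final_transcripts: Set[str] = field(default_factory=set)
    expected_excluded_transcripts: Set[str] = field(default_factory=set)
    expected_venn_transcripts: Dict[str, int] = field(default_factory=dict)
    expected_venn_introns: Dict[str, int] = field(default_factory=dict)
    expected_error_matrix: Dict[str, Dict[str, int]] = field(default_factory=dict)
    expected_mechanism: Dict[str, int] = field(default_factory=dict)
    expected_support_k: Dict[str, int] = field(default_factory=dict)  # "chrom:pos:ref:alt" -> k
    expected_known: Dict[str, bool] = field(default_factory=dict)
    expected_genotype_counts: Dict[str, int] = field(default_factory=dict)
    expected_alignment_kept: int = 0
    n_loci: int = 0
    loci_min2_exons: int = 0
    loci_min3_exons: int = 0

    def planted_error_keys(self) -> Set[Tuple[str, int, str, str]]:
        return {p.key for p in self.planted if p.group == "planted_error"}

    def to_json(self) -> str:
        def _enc(obj):
            if isinstance(obj, (set, frozenset)):
                return sorted(obj)
            if isinstance(obj, TranscriptModel):
                return obj.transcript_id
            if isinstance(obj, PlantedVariant):
                d = asdict(obj)
                d["key"] = list(d["key"])
                return d
            raise TypeError(type(obj))

        payload = {
            "true_transcripts": [t.transcript_id for t in self.true_transcripts],
            "fragment_parents": self.fragment_parents,
            "true_links": [list(x) for x in self.true_links],
            "planted": [_enc(p) for p in self.planted],
            "gene_membership": {k: sorted(v) for k, v in self.gene_membership.items()},
            "expected_filter_fail": self.expected_filter_fail,
            "expected_genomic_filter_fail": self.expected_genomic_filter_fail,
            "expected_final_transcripts": sorted(self.expected_final_transcripts),
            "expected_excluded_transcripts": sorted(self.expected_excluded_transcripts),
            "expected_venn_transcripts": self.expected_venn_transcripts,
            "expected_venn_introns": self.expected_venn_introns,
            "expected_error_matrix": self.expected_error_matrix,
            "expected_mechanism": self.expected_mechanism,
            "expected_support_k": self.expected_support_k,
            "expected_known": self.expected_known,
            "expected_genotype_counts": self.expected_genotype_counts,
            "expected_alignment_kept": self.expected_alignment_kept,
            "n_loci": self.n_loci,
            "loci_min2_exons": self.loci_min2_exons,
            "loci_min3_exons": self.loci_min3_exons,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def key_str(key: Tuple[str, int, str, str]) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


@dataclass
class _GeneDesign:
    index: int
    role: str  # frag / err_snp / err_ins / err_del / err_mimic / het_* / unsup_* / neutral_host / plain / single / twoexon
    strand: str
    exon_lengths: List[int]
    intron_lengths: List[int]
    intron_sites: List[Tuple[str, str]]
    ref_spliced: str  # reference-genome-side mRNA (transcript orientation)
    truth_spliced: str  # RNA-side mRNA
    # mRNA-level edit describing RNA relative to the reference copy:
    # ("del", start, length) / ("ins", after_offset, inserted_seq) / ("snp", offset, alt_base)
    edit: Optional[Tuple] = None
    split_intron_index: Optional[int] = None
    mimic_region: Optional[Tuple[int, int]] = None  # reference-mRNA offsets of X
    # filled during layout:
    chrom: str = ""
    gene_start: int = 0
    model: Optional[TranscriptModel] = None


@dataclass
class SimulatedDataset:
    """All emitted inputs plus the TruthSet."""

    config: SimulationConfig
    genome: GenomeSequence
    annotation_sets: List[AnnotationSet]
    annotation_beds: Dict[str, str]
    truth_transcripts: List[TranscriptModel]
    assembled_transcripts: List[TranscriptModel]
    long_reads: List[ReadRecord]
    alignments: List[AlignmentRecord]
    junctions: List[JunctionRecord]
    rna_records: List[VariantRecord]
    genomic_records: List[VariantRecord]
    known_records: List[VariantRecord]
    comparison_records: List[List[VariantRecord]]
    evidence: Dict[str, str]
    truth: TruthSet

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)

        def _write(name: str, text: str) -> None:
            with open(os.path.join(out_dir, name), "w") as fh:
                fh.write(text)

        _write("genome.fa", txio.write_fasta(self.genome))
        _write("assembled.gtf", txio.write_gtf(self.assembled_transcripts))
        _write("truth.gtf", txio.write_gtf(self.truth_transcripts))
        for label, text in self.annotation_beds.items():
            _write(f"annotation_{label}.bed", text)
        _write("long_reads.fastq", txio.write_fastq(self.long_reads))
        _write("alignments.tsv", txio.write_alignment_tsv(self.alignments))
        _write("junctions.tsv", txio.write_junction_tsv(self.junctions))
        _write("rna.vcf", txio.write_vcf(self.rna_records))
        _write("genomic.vcf", txio.write_vcf(self.genomic_records))
        _write("known.vcf", txio.write_vcf(self.known_records))
        for i, records in enumerate(self.comparison_records, 1):
            _write(f"comparison_{i}.vcf", txio.write_vcf(records))
        _write("evidence.fa", txio.write_fasta(self.evidence))
        _write("truth.json", self.truth.to_json() + "\n")


class Simulation:
    """Stateful builder; the stage methods mirror the generator operations."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.designs: List[_GeneDesign] = []
        self.genome: GenomeSequence = {}
        self.annotation_sets: List[AnnotationSet] = []
        self.annotation_beds: Dict[str, str] = {}
        self.truth = TruthSet()
        self.gene_models: List[TranscriptModel] = []
        self.noise_models: List[TranscriptModel] = []
        self.assembled: List[TranscriptModel] = []
        self.long_reads: List[ReadRecord] = []
        self.alignments: List[AlignmentRecord] = []
        self.junctions: List[JunctionRecord] = []
        self.rna_records: List[VariantRecord] = []
        self.genomic_records: List[VariantRecord] = []
        self.known_records: List[VariantRecord] = []
        self.comparison_records: List[List[VariantRecord]] = []
        self.evidence: Dict[str, str] = {}

    # ------------------------------------------------------------------
    # helpers

    def _random_seq(self, n: int) -> str:
        return "".join(np.array(list(BASES))[self.rng.integers(0, 4, n)])

    def _random_utr(self, n: int) -> str:
        seq = list(self._random_seq(n))
        # suppress spurious start codons so designed ORFs dominate
        for i in range(len(seq) - 2):
            if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G":
                seq[i + 2] = "C"
        return "".join(seq)

    def _random_codons(self, n: int) -> List[str]:
        idx = self.rng.integers(0, len(NONSTOP_CODONS), n)
        return [NONSTOP_CODONS[i] for i in idx]

    # ------------------------------------------------------------------
    # stage 1: genome, annotations, truth skeleton

    def generate_reference_and_truth(self):
        cfg = self.config
        roles = self._assign_roles()
        for i, role in enumerate(roles):
            self.designs.append(self._design_gene(i, role))
        self._layout_genome()
        self._build_annotations()
        self.truth.true_transcripts = list(self.gene_models)
        for d in self.designs:
            self.truth.gene_membership[d.model.transcript_id] = self._membership[d.index]
        return self.genome, self.annotation_sets, self.truth

    def _assign_roles(self) -> List[str]:
        cfg = self.config
        roles: List[str] = []
        roles += ["frag"] * cfg.n_fragmented_transcripts
        roles += ["err_snp"] * cfg.n_planted_snp_errors
        roles += ["err_ins"] * cfg.n_planted_ins_errors
        roles += ["err_del"] * max(cfg.n_planted_del_errors - 1, 0)
        if cfg.n_planted_del_errors > 0:
            roles += ["err_mimic"]
        het_classes = ["snp", "ins", "del"]
        roles += [f"het_{het_classes[i % 3]}" for i in range(cfg.n_het_decoys)]
        roles += [f"unsup_{het_classes[i % 3]}" for i in range(cfg.n_unsupported_decoys)]
        roles += ["single"] * cfg.n_single_exon_genes
        roles += ["twoexon"] * cfg.n_two_exon_genes
        if len(roles) > cfg.n_genes:
            raise ValueError(
                f"infeasible config: {len(roles)} role genes exceed n_genes={cfg.n_genes}"
            )
        roles += ["plain"] * (cfg.n_genes - len(roles))
        return roles

    def _design_gene(self, index: int, role: str) -> _GeneDesign:
        for _attempt in range(50):
            design = self._try_design_gene(index, role)
            if design is not None:
                return design
        raise RuntimeError(f"could not design gene {index} with role {role!r}")

    def _try_design_gene(self, index: int, role: str) -> Optional[_GeneDesign]:
        cfg = self.config
        rng = self.rng
        lo, hi = cfg.exon_count_range
        if role == "frag":
            k = int(rng.integers(max(3, lo), hi + 1))
        elif role == "single":
            k = 1
        elif role == "twoexon":
            k = 2
        elif role.startswith(("err", "het", "unsup")):
            k = int(rng.integers(max(2, lo), hi + 1))
        else:
            k = int(rng.integers(lo, hi + 1))
        if role == "single":
            exon_lengths = [int(rng.integers(350, 501))]
        else:
            exon_lengths = [
                int(x) for x in rng.integers(cfg.exon_length_range[0], cfg.exon_length_range[1] + 1, k)
            ]
        l_ref = sum(exon_lengths)
        strand = "+" if rng.random() < 0.5 else "-"

        # reference-vs-truth length delta (reference = truth + delta)
        if role in ("err_del", "het_del", "unsup_del"):
            delta = 1
        elif role in ("err_ins", "het_ins", "unsup_ins"):
            delta = -1
        elif role == "err_mimic":
            delta = cfg.mimic_deletion_length
        else:
            delta = 0
        l_truth = l_ref - delta
        u5 = int(rng.integers(30, 61))
        u3 = int(rng.integers(30, 61))
        ncod = (l_truth - u5 - u3 - 6) // 3
        if ncod < 40:
            return None
        u3 = l_truth - u5 - 6 - 3 * ncod + u3  # absorb rounding into the 3' UTR
        u3 = l_truth - (u5 + 3 + 3 * ncod + 3)
        codons = self._random_codons(ncod)

        edit = None
        mimic_region = None
        needs_site = role.startswith(("err", "het", "unsup")) or role == "neutral_host"
        variant_kind = None
        if role.endswith("snp") and needs_site:
            variant_kind = "snp"
        elif role.endswith("ins"):
            variant_kind = "ins"
        elif role.endswith("del"):
            variant_kind = "del"
        elif role == "err_mimic":
            variant_kind = "mimic"

        boundaries = np.cumsum([0] + exon_lengths)

        def region_in_one_exon(a: int, b: int) -> bool:
            for s, e in zip(boundaries[:-1], boundaries[1:]):
                if s + 2 <= a and b <= e - 2:
                    return True
            return False

        ci = None
        if variant_kind is not None:
            candidates = list(range(max(2, int(0.2 * ncod)), max(3, int(0.6 * ncod))))
            span = {"snp": 9, "ins": 9, "del": 9, "mimic": cfg.mimic_deletion_length + 8}[variant_kind]
            for c in candidates:
                a = u5 + 3 + 3 * (c - 1)
                if region_in_one_exon(a, a + span) and c + 7 < ncod:
                    ci = c
                    break
            if ci is None:
                return None

        if variant_kind in ("ins", "del", "mimic"):
            codons[ci - 1] = "GAT"
            for gi, guard in enumerate(FRAMESHIFT_GUARD):
                codons[ci + 2 + gi] = guard
        if variant_kind == "del":
            codons[ci] = "CCC"
            codons[ci + 1] = "CAT"
        elif variant_kind == "ins":
            codons[ci] = "CCC"
            codons[ci + 1] = "CCA"
        elif variant_kind == "snp":
            codons[ci] = "TGG"

        truth = self._random_utr(u5) + "ATG" + "".join(codons) + "TAA" + self._random_utr(u3)
        assert len(truth) == l_truth

        ref = truth
        if variant_kind == "snp":
            off = u5 + 3 + 3 * ci + 2  # third base of the TGG codon
            ref = truth[:off] + "A" + truth[off + 1 :]  # reference reads TGA (stop)
            edit = ("snp", off, "G")
        elif variant_kind == "del":
            r0 = u5 + 3 + 3 * ci  # start of the truth CCCC run
            ref = truth[:r0] + "C" + truth[r0:]  # reference carries CCCCC
            edit = ("del", r0, 1)
        elif variant_kind == "ins":
            r0 = u5 + 3 + 3 * ci  # start of the truth CCCCC run
            ref = truth[:r0] + truth[r0 + 1 :]  # reference carries CCCC
            edit = ("ins", r0 + 3, "C")  # reinsert after the reference run
        elif variant_kind == "mimic":
            x0 = u5 + 3 + 3 * ci
            x_seq = "TAA" + self._random_seq(cfg.mimic_deletion_length - 6) + "CCG"
            ref = truth[:x0] + x_seq + truth[x0:]
            edit = ("del", x0, cfg.mimic_deletion_length)
            mimic_region = (x0, x0 + cfg.mimic_deletion_length)
        elif role == "plain" or role in ("frag", "single", "twoexon"):
            pass
        assert len(ref) == l_ref

        # generator self-check: the RNA-side correction must extend the ORF
        if variant_kind is not None:
            ref_orf = longest_orf(ref)
            truth_orf = longest_orf(truth)
            ref_len = ref_orf.length if ref_orf else 0
            truth_len = truth_orf.length if truth_orf else 0
            if truth_len <= ref_len:
                return None

        intron_lengths = [
            int(x)
            for x in self.rng.integers(
                cfg.intron_length_range[0], cfg.intron_length_range[1] + 1, max(k - 1, 0)
            )
        ]
        sites = []
        for j in range(max(k - 1, 0)):
            if self.rng.random() < cfg.fraction_noncanonical_introns:
                sites.append(NONCANONICAL_SITES[int(self.rng.integers(0, len(NONCANONICAL_SITES)))])
            else:
                sites.append(("GT", "AG"))
        split = None
        if role == "frag":
            split = (k - 1) // 2
            if index < 2:
                # guarantee the non-canonical-junction merge path is exercised
                sites[split] = NONCANONICAL_SITES[0]
        return _GeneDesign(
            index=index,
            role=role,
            strand=strand,
            exon_lengths=exon_lengths,
            intron_lengths=intron_lengths,
            intron_sites=sites,
            ref_spliced=ref,
            truth_spliced=truth,
            edit=edit,
            split_intron_index=split,
            mimic_region=mimic_region,
        )

    def _layout_genome(self) -> None:
        cfg = self.config
        rng = self.rng
        chrom_arrays = {
            name: np.array(list(self._random_seq(cfg.chrom_length))) for name in cfg.chrom_names
        }
        cursors = {name: 3000 for name in cfg.chrom_names}
        self._gaps: List[Tuple[str, int, int]] = []
        for d in self.designs:
            chrom = cfg.chrom_names[d.index % len(cfg.chrom_names)]
            # sense layout: exon/intron alternation in transcript order
            pieces: List[str] = []
            exon_sense_bounds: List[Tuple[int, int]] = []
            pos = 0
            off = 0
            for j, elen in enumerate(d.exon_lengths):
                pieces.append(d.ref_spliced[off : off + elen])
                exon_sense_bounds.append((pos, pos + elen))
                pos += elen
                off += elen
                if j < len(d.exon_lengths) - 1:
                    ilen = d.intron_lengths[j]
                    donor, acceptor = d.intron_sites[j]
                    pieces.append(donor + self._random_seq(ilen - 4) + acceptor)
                    pos += ilen
            sense = "".join(pieces)
            region = sense if d.strand == "+" else revcomp(sense)
            start = cursors[chrom]
            end = start + len(region)
            if end > cfg.chrom_length - 3000:
                raise ValueError(
                    "infeasible config: genes do not fit on the chromosomes"
                )
            chrom_arrays[chrom][start:end] = list(region)
            gap = int(rng.integers(1800, 3001))
            self._gaps.append((chrom, end + 300, end + gap - 300))
            cursors[chrom] = end + gap
            d.chrom = chrom
            d.gene_start = start
            exons = []
            n = len(region)
            for s, e in exon_sense_bounds:
                if d.strand == "+":
                    exons.append(ExonInterval(chrom, start + s, start + e, d.strand))
                else:
                    exons.append(ExonInterval(chrom, start + (n - e), start + (n - s), d.strand))
            tid = f"TX{d.index:04d}"
            d.model = TranscriptModel(
                transcript_id=tid,
                exons=exons,
                strand=d.strand,
                gene_id=f"G{d.index:04d}",
            )
        self.genome = {name: "".join(arr) for name, arr in chrom_arrays.items()}
        self.gene_models = [d.model for d in self.designs]
        # consistency: the genome-derived spliced sequence must equal the design
        for d in self.designs:
            ts = build_transcript_sequence(d.model, self.genome)
            assert ts.sequence == d.ref_spliced, d.model.transcript_id
        # noise transcripts in intergenic gaps
        self.noise_models = []
        usable = [g for g in self._gaps if g[2] - g[1] > 400]
        for j in range(self.config.n_noise_transcripts):
            chrom, gs, ge = usable[j % len(usable)]
            length = int(rng.integers(250, 351))
            offset = int(rng.integers(0, max(ge - gs - length, 1)))
            s = gs + offset
            strand = [".", "+", "-"][j % 3]
            self.noise_models.append(
                TranscriptModel(
                    transcript_id=f"NOISE{j:02d}",
                    exons=[ExonInterval(chrom, s, s + length, strand)],
                    strand=strand,
                    gene_id=f"NG{j:02d}",
                )
            )

    def _build_annotations(self) -> None:
        rng = self.rng
        regions = list(VENN_REGIONS_PROBS)
        probs = np.array(list(VENN_REGIONS_PROBS.values()))
        probs = probs / probs.sum()
        self._membership: List[FrozenSet[str]] = []
        for d in self.designs:
            member = regions[int(rng.choice(len(regions), p=probs))]
            if d.role in ("frag", "err_mimic") and not member:
                # links are only acceptable when the implied intron is
                # annotated, and the intron-mimic diagnostic is defined
                # relative to annotated introns, so these hosts must be
                # annotated genes
                member = regions[int(rng.choice(len(regions) - 1, p=probs[:-1] / probs[:-1].sum()))]
            self._membership.append(frozenset(member))
        bed_lines: Dict[str, List[str]] = {"Ensembl": [], "RefSeq": [], "OtherRefSeq": []}
        for d, member in zip(self.designs, self._membership):
            ann_model = self._annotation_model(d)
            for source in member:
                bed_lines[source].append(
                    txio.bed12_line(ann_model, name=f"{source}_{d.model.gene_id}")
                )
        self.annotation_beds = {
            label: "\n".join(lines) + ("\n" if lines else "") for label, lines in bed_lines.items()
        }
        self.annotation_sets = [
            txio.parse_bed12(text, label) for label, text in self.annotation_beds.items()
        ]

    def _annotation_model(self, d: _GeneDesign) -> TranscriptModel:
        """Annotated structure of a gene; for the mimic host the annotation
        splices out the spurious reference insertion as an intron."""
        if d.mimic_region is None:
            return d.model
        ts = build_transcript_sequence(d.model, self.genome)
        a, b = d.mimic_region
        gpos = sorted(ts.genomic_positions[a:b])
        gx_start, gx_end = gpos[0], gpos[-1] + 1
        exons: List[ExonInterval] = []
        for exon in d.model.exons:
            if exon.start <= gx_start and gx_end <= exon.end:
                exons.append(ExonInterval(exon.chrom, exon.start, gx_start, exon.strand))
                exons.append(ExonInterval(exon.chrom, gx_end, exon.end, exon.strand))
            else:
                exons.append(exon)
        return TranscriptModel(
            transcript_id=d.model.transcript_id + "_ann",
            exons=exons,
            strand=d.strand,
            gene_id=d.model.gene_id,
        )

    # ------------------------------------------------------------------
    # stage 2: fragmented assembly + junction catalogue + evidence

    def fragment_transcripts(self) -> List[TranscriptModel]:
        assembled: List[TranscriptModel] = []
        for d in self.designs:
            if d.role == "frag":
                si = d.split_intron_index
                frag_a = TranscriptModel(
                    transcript_id=d.model.transcript_id + "a",
                    exons=d.model.exons[: si + 1],
                    strand=d.strand,
                    gene_id=d.model.gene_id,
                )
                frag_b = TranscriptModel(
                    transcript_id=d.model.transcript_id + "b",
                    exons=d.model.exons[si + 1 :],
                    strand=d.strand,
                    gene_id=d.model.gene_id,
                )
                assembled.extend([frag_a, frag_b])
                self.truth.fragment_parents[frag_a.transcript_id] = d.model.transcript_id
                self.truth.fragment_parents[frag_b.transcript_id] = d.model.transcript_id
                self.truth.true_links.append(
                    (d.model.transcript_id, frag_a.transcript_id, frag_b.transcript_id)
                )
            else:
                assembled.append(d.model)
        assembled.extend(self.noise_models)
        self.assembled = assembled
        self._build_junctions()
        return assembled

    def _build_junctions(self) -> None:
        junctions: List[JunctionRecord] = []
        seen = set()
        intron_sources: List[Tuple[IntronKey, str]] = []
        for t in self.assembled:
            for intron in t.introns():
                intron_sources.append((intron, t.strand))
        for d in self.designs:
            if d.role == "frag":
                parent_introns = d.model.introns()
                intron_sources.append((parent_introns[d.split_intron_index], d.strand))
        n = 0
        for intron, strand in intron_sources:
            key = (intron.chrom, intron.start, intron.end)
            if key in seen:
                continue
            seen.add(key)
            n += 1
            dinuc = junction_dinucleotides(
                self.genome, intron.chrom, intron.start, intron.end, strand
            )
            junctions.append(
                JunctionRecord(
                    chrom=intron.chrom,
                    donor_end=intron.start,
                    acceptor_start=intron.end,
                    strand=strand,
                    dinucleotides=dinuc,
                    name=f"jct{n:04d}",
                    support=int(self.rng.integers(3, 21)),
                )
            )
        junctions.sort(key=lambda j: (j.chrom, j.donor_end, j.acceptor_start))
        self.junctions = junctions

    # ------------------------------------------------------------------
    # stage 3: long reads + short-read alignment records

    def simulate_reads(self):
        cfg = self.config
        rng = self.rng
        for d in self.designs:
            if d.role != "frag":
                continue
            ts = build_transcript_sequence(d.model, self.genome)
            si = d.split_intron_index
            upstream_exons = si + 1 if d.strand != "-" else len(d.exon_lengths) - si - 1
            if d.strand != "-":
                lu = sum(e.length for e in d.model.exons[: si + 1])
            else:
                lu = sum(e.length for e in d.model.exons[si + 1 :])
            total = len(ts.sequence)
            for r in range(cfg.n_linking_reads):
                u = int(rng.integers(30, min(61, lu + 1)))
                v = int(rng.integers(30, min(61, total - lu + 1)))
                seq = ts.sequence[lu - u : lu + v]
                seq = self._apply_read_errors(seq)
                self.long_reads.append(
                    ReadRecord(
                        read_id=f"link_{d.model.transcript_id}_{r}",
                        sequence=seq,
                        quality="I" * len(seq),
                    )
                )
        # decoy reads contained in single transcripts (no links implied)
        hosts = [t for t in self.assembled if t.spliced_length >= 120]
        for j in range(cfg.n_decoy_reads):
            host = hosts[int(rng.integers(0, len(hosts)))]
            ts = build_transcript_sequence(host, self.genome)
            length = int(rng.integers(60, 91))
            start = int(rng.integers(0, len(ts.sequence) - length + 1))
            seq = self._apply_read_errors(ts.sequence[start : start + length])
            if j < 2:
                quality = "5" * len(seq)  # mean phred 20: filtered by quality
            else:
                quality = "I" * len(seq)
            self.long_reads.append(
                ReadRecord(read_id=f"decoy_{j:02d}", sequence=seq, quality=quality)
            )
        # one too-short read, skipped by the length rule
        self.long_reads.append(
            ReadRecord(read_id="short_00", sequence=self._random_seq(40), quality="I" * 40)
        )
        self._simulate_alignments()
        self._build_evidence()
        return self.long_reads, self.alignments

    def _apply_read_errors(self, seq: str) -> str:
        rate = self.config.read_error_rate
        if rate <= 0:
            return seq
        chars = list(seq)
        errors = np.nonzero(self.rng.random(len(chars)) < rate)[0]
        # keep end segments alignable: at most one substitution per 25 bp end
        used_5p = used_3p = 0
        for i in errors:
            if i < 25:
                if used_5p:
                    continue
                used_5p += 1
            if i >= len(chars) - 25:
                if used_3p:
                    continue
                used_3p += 1
            options = [b for b in BASES if b != chars[i]]
            chars[i] = options[int(self.rng.integers(0, 3))]
        return "".join(chars)

    def _simulate_alignments(self) -> None:
        rng = self.rng
        kept = 0
        records: List[AlignmentRecord] = []
        for i in range(20):
            mm = int(rng.integers(0, 6))
            records.append(
                AlignmentRecord(
                    read_id=f"sr{i:03d}",
                    chrom=self.config.chrom_names[i % len(self.config.chrom_names)],
                    pos=int(rng.integers(0, self.config.chrom_length - 100)),
                    strand="+" if i % 2 == 0 else "-",
                    mismatch_count=mm,
                )
            )
            if mm <= 3:
                kept += 1
        for i in range(6):
            pos = int(rng.integers(1000, self.config.chrom_length - 2000))
            if i < 3:  # proper pairs
                chrom_b, strand_b, pos_b = self.config.chrom_names[0], "-", pos + int(rng.integers(150, 400))
                kept += 2
            elif i < 5:  # same-strand or cross-chromosome: improper
                chrom_b = self.config.chrom_names[0] if i == 3 else self.config.chrom_names[1]
                strand_b = "+" if i == 3 else "-"
                pos_b = pos + 200
            else:
                chrom_b = None  # orphan: second mate never emitted
            records.append(
                AlignmentRecord(
                    read_id=f"pr{i:03d}",
                    mate_index=0,
                    chrom=self.config.chrom_names[0],
                    pos=pos,
                    strand="+",
                    mismatch_count=int(rng.integers(0, 3)),
                )
            )
            if chrom_b is not None:
                records.append(
                    AlignmentRecord(
                        read_id=f"pr{i:03d}",
                        mate_index=1,
                        chrom=chrom_b,
                        pos=pos_b,
                        strand=strand_b,
                        mismatch_count=int(rng.integers(0, 3)),
                    )
                )
        self.alignments = records
        self.truth.expected_alignment_kept = kept

    def _build_evidence(self) -> None:
        # the evidence database stands in for the pooled long reads plus
        # cross-species protein-coding cDNA collection
        for d in self.designs:
            self.evidence[f"cdna_{d.model.gene_id}"] = d.ref_spliced
        for read in self.long_reads:
            if read.read_id.startswith("link_"):
                self.evidence[f"lr_{read.read_id}"] = read.sequence

    # ------------------------------------------------------------------
    # stage 4: variant call sets

    def simulate_variants_and_vcfs(self):
        cfg = self.config
        rng = self.rng
        planted: List[PlantedVariant] = []
        rec_n = 0

        def _passing_info(genomic: bool = False) -> Dict[str, float]:
            info = {
                "QD": round(float(rng.uniform(5, 30)), 2),
                "MQ": round(float(rng.uniform(50, 60)), 2),
                "FS": round(float(rng.uniform(0, 10)), 2),
                "MQRankSum": round(float(rng.uniform(-2, 2)), 2),
                "ReadPosRankSum": round(float(rng.uniform(-2, 2)), 2),
            }
            if genomic:
                info["HaplotypeScore"] = round(float(rng.uniform(0, 5)), 2)
            return info

        group_of_role = {
            "err_snp": "planted_error",
            "err_ins": "planted_error",
            "err_del": "planted_error",
            "err_mimic": "planted_error",
            "het_snp": "het_decoy",
            "het_ins": "het_decoy",
            "het_del": "het_decoy",
            "unsup_snp": "unsupported_decoy",
            "unsup_ins": "unsupported_decoy",
            "unsup_del": "unsupported_decoy",
        }
        slip_runs: Dict[Tuple[str, int, str, str], Tuple[int, int, str]] = {}
        for d in self.designs:
            group = group_of_role.get(d.role)
            if group is None:
                continue
            rec_n += 1
            rid = f"rna{rec_n:03d}"
            pos, ref, alt, run = self._edit_to_genomic(d)
            key = (d.chrom, pos, ref, alt)
            if run is not None:
                slip_runs[key] = run
            cls = VariantRecord(chrom=d.chrom, pos=pos, ref_allele=ref, alt_alleles=[alt]).allele_class()
            slip = cls in ("insertion", "deletion") and run is not None
            mimic = d.role == "err_mimic"
            planted.append(
                PlantedVariant(
                    record_id=rid,
                    key=key,
                    variant_class=cls,
                    group=group,
                    host_transcript_id=d.model.transcript_id,
                    homopolymer_slip=slip,
                    intron_mimic=mimic,
                )
            )
            gt = (1, 1) if group == "planted_error" else (0, 1)
            ad = [int(rng.integers(0, 6)), int(rng.integers(20, 61))] if gt == (1, 1) else [
                int(rng.integers(15, 30)),
                int(rng.integers(15, 30)),
            ]
            self.rna_records.append(
                VariantRecord(
                    chrom=d.chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_alleles=[alt],
                    genotype=gt,
                    info_metrics=_passing_info(),
                    allele_depths=ad,
                    record_id=rid,
                )
            )
            self.truth.expected_filter_fail[rid] = []

        # neutral 3'-UTR polymorphisms across non-variant host genes
        neutral_hosts = [d for d in self.designs if d.role in ("plain", "single", "twoexon", "frag")]
        neutral_done = 0
        gi = 0
        genotypes = [(1, 1)] * 5 + [(0, 1)] * 5 + [(1, 2)] * 2
        while neutral_done < cfg.n_neutral_variants and gi < 400:
            gi += 1
            d = neutral_hosts[int(rng.integers(0, len(neutral_hosts)))]
            result = self._design_neutral_snp(d)
            if result is None:
                continue
            pos, ref, alts = result
            gt = genotypes[neutral_done % len(genotypes)]
            if max(gt) == 1:
                alts = alts[:1]
            rec_n += 1
            rid = f"rna{rec_n:03d}"
            host = (
                d.model.transcript_id
                if d.role != "frag"
                else d.model.transcript_id  # merged parent carries the variant
            )
            for ai, alt in enumerate(alts):
                planted.append(
                    PlantedVariant(
                        record_id=rid,
                        key=(d.chrom, pos, ref, alt),
                        variant_class="snp",
                        group="neutral",
                        host_transcript_id=host,
                    )
                )
            self.rna_records.append(
                VariantRecord(
                    chrom=d.chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_alleles=alts,
                    genotype=gt,
                    info_metrics=_passing_info(),
                    allele_depths=[int(rng.integers(10, 40)) for _ in range(1 + len(alts))],
                    record_id=rid,
                )
            )
            self.truth.expected_filter_fail[rid] = []
            neutral_done += 1

        # records violating exactly one hard-filter rule each
        fail_specs = [
            ("snp", "QD", 1.0),
            ("snp", "MQ", 30.0),
            ("snp", "FS", 70.0),
            ("snp", "MQRankSum", -13.0),
            ("snp", "ReadPosRankSum", -9.0),
            ("indel", "QD", 1.5),
            ("indel", "FS", 250.0),
            ("indel", "ReadPosRankSum", -25.0),
        ]
        used_positions = {(r.chrom, r.pos) for r in self.rna_records}
        for i in range(cfg.n_failing_records):
            cls, metric, value = fail_specs[i % len(fail_specs)]
            chrom = cfg.chrom_names[i % len(cfg.chrom_names)]
            while True:
                g = int(rng.integers(100, 2500))  # upstream of the first gene
                if (chrom, g + 1) not in used_positions:
                    break
            used_positions.add((chrom, g + 1))
            seq = self.genome[chrom]
            if cls == "snp":
                ref = seq[g]
                alt = BASES[(BASES.index(ref) + 1) % 4]
            else:
                ref = seq[g : g + 2]
                alt = seq[g]
            info = _passing_info()
            info[metric] = value
            rec_n += 1
            rid = f"rna{rec_n:03d}"
            self.rna_records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=g + 1,
                    ref_allele=ref,
                    alt_alleles=[alt],
                    genotype=(0, 1),
                    info_metrics=info,
                    allele_depths=[20, 10],
                    record_id=rid,
                )
            )
            self.truth.expected_filter_fail[rid] = [metric]

        self.truth.planted = planted
        self.rna_records.sort(key=lambda r: (r.chrom, r.pos, r.record_id))

        # genomic resequencing of the reference individual
        gn = 0
        for p in planted:
            if p.group not in ("planted_error", "het_decoy"):
                continue
            gn += 1
            chrom, pos, ref, alt = p.key
            if p.homopolymer_slip and gn % 2 == 0 and p.key in slip_runs:
                pos, ref, alt = self._rightmost_representation(chrom, *slip_runs[p.key])
            gt = (1, 1) if p.group == "planted_error" else (0, 1)
            rid = f"gen{gn:03d}"
            self.genomic_records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_alleles=[alt],
                    genotype=gt,
                    info_metrics=_passing_info(genomic=True),
                    allele_depths=[0, int(rng.integers(15, 40))] if gt == (1, 1) else [18, 17],
                    record_id=rid,
                )
            )
            self.truth.expected_genomic_filter_fail[rid] = []
        # one genomic record failing the genomic-only HaplotypeScore rule
        g = int(rng.integers(100, 2000))
        seq = self.genome[cfg.chrom_names[0]]
        info = _passing_info(genomic=True)
        info["HaplotypeScore"] = 20.0
        gn += 1
        rid = f"gen{gn:03d}"
        self.genomic_records.append(
            VariantRecord(
                chrom=cfg.chrom_names[0],
                pos=g + 1,
                ref_allele=seq[g],
                alt_alleles=[BASES[(BASES.index(seq[g]) + 2) % 4]],
                genotype=(0, 1),
                info_metrics=info,
                allele_depths=[12, 11],
                record_id=rid,
            )
        )
        self.truth.expected_genomic_filter_fail[rid] = ["HaplotypeScore"]
        self.genomic_records.sort(key=lambda r: (r.chrom, r.pos, r.record_id))

        # comparison datasets and the "previously annotated" set
        alleles = []
        for p in planted:
            alleles.append(p)
        for p in alleles:
            self.truth.expected_support_k[key_str(p.key)] = 0
        for j in range(cfg.n_comparison_datasets):
            records: List[VariantRecord] = []
            for p in alleles:
                if rng.random() >= cfg.fraction_of_errors_shared:
                    continue
                chrom, pos, ref, alt = p.key
                if p.homopolymer_slip and j % 2 == 1 and p.key in slip_runs:
                    pos, ref, alt = self._rightmost_representation(chrom, *slip_runs[p.key])
                records.append(
                    VariantRecord(
                        chrom=chrom,
                        pos=pos,
                        ref_allele=ref,
                        alt_alleles=[alt],
                        genotype=(1, 1),
                        info_metrics={},
                        allele_depths=None,
                        record_id=f"cmp{j + 1}_{key_str(p.key)}",
                    )
                )
                self.truth.expected_support_k[key_str(p.key)] += 1
            records.sort(key=lambda r: (r.chrom, r.pos))
            self.comparison_records.append(records)
        kn = 0
        for p in alleles:
            known = bool(rng.random() < cfg.known_fraction)
            self.truth.expected_known[key_str(p.key)] = known
            if known:
                kn += 1
                chrom, pos, ref, alt = p.key
                self.known_records.append(
                    VariantRecord(
                        chrom=chrom,
                        pos=pos,
                        ref_allele=ref,
                        alt_alleles=[alt],
                        genotype=(1, 1),
                        info_metrics={},
                        record_id=f"known{kn:03d}",
                    )
                )
        self.known_records.sort(key=lambda r: (r.chrom, r.pos))
        self._fill_expected_summaries()
        return self.rna_records, self.genomic_records, self.comparison_records

    def _edit_to_genomic(self, d: _GeneDesign):
        """Convert the gene's mRNA-level edit into a normalized genomic
        (pos, ref, alt), plus homopolymer run bounds for indels."""
        ts = build_transcript_sequence(d.model, self.genome)
        chrom_seq = self.genome[d.chrom]
        kind = d.edit[0]
        if kind == "snp":
            _, off, alt_base = d.edit
            g = ts.genomic_positions[off]
            ref = chrom_seq[g]
            alt = alt_base if d.strand != "-" else revcomp(alt_base)
            assert ref != alt
            pos, ref, alt = normalize_allele(self.genome, d.chrom, g + 1, ref, alt)
            return pos, ref, alt, None
        if kind == "del":
            _, start, length = d.edit
            gpos = sorted(ts.genomic_positions[start : start + length])
            gmin, gmax = gpos[0], gpos[-1]
            assert gmax - gmin + 1 == length
            raw_pos = gmin  # 1-based anchor at 0-based gmin-1
            ref = chrom_seq[gmin - 1 : gmax + 1]
            alt = chrom_seq[gmin - 1]
            pos, ref, alt = normalize_allele(self.genome, d.chrom, raw_pos, ref, alt)
            run = self._run_bounds(chrom_seq, pos) if length == 1 else None
            return pos, ref, alt, run
        if kind == "ins":
            _, after, inserted = d.edit
            if d.strand != "-":
                g = ts.genomic_positions[after]
                ins_seq = inserted
            else:
                g = ts.genomic_positions[after + 1]
                ins_seq = revcomp(inserted)
            ref = chrom_seq[g]
            alt = ref + ins_seq
            pos, ref, alt = normalize_allele(self.genome, d.chrom, g + 1, ref, alt)
            run = self._run_bounds_insertion(chrom_seq, pos, alt[1])
            return pos, ref, alt, run
        raise AssertionError(kind)

    @staticmethod
    def _run_bounds(chrom_seq: str, pos: int) -> Tuple[int, int, str]:
        """Homopolymer run containing the deleted base (0-based half-open)."""
        base = chrom_seq[pos]  # first deleted base, 0-based == 1-based anchor pos
        s = pos
        while s > 0 and chrom_seq[s - 1] == base:
            s -= 1
        e = pos
        while e < len(chrom_seq) and chrom_seq[e] == base:
            e += 1
        return s, e, "del"

    @staticmethod
    def _run_bounds_insertion(chrom_seq: str, pos: int, base: str) -> Tuple[int, int, str]:
        s = pos  # run begins at the base after the anchor (0-based pos)
        e = pos
        while e < len(chrom_seq) and chrom_seq[e] == base:
            e += 1
        return s, e, "ins"

    def _rightmost_representation(self, chrom: str, s: int, e: int, kind: str):
        """Express a 1 bp homopolymer indel at the 3' end of its run."""
        seq = self.genome[chrom]
        if kind == "del":
            if e - s < 2:
                return s, seq[s - 1 : s + 1], seq[s - 1]
            return e - 1, seq[e - 2 : e], seq[e - 2]
        # insertion: anchor at the last run base
        base = seq[e - 1] if e > s else seq[s - 1]
        if e == s:
            return s, seq[s - 1], seq[s - 1] + base
        return e, seq[e - 1], seq[e - 1] + base

    def _design_neutral_snp(self, d: _GeneDesign):
        """A 3'-UTR SNP with no effect on the longest ORF (self-checked)."""
        ts = build_transcript_sequence(d.model, self.genome)
        seq = ts.sequence
        n = len(seq)
        for _ in range(8):
            off = n - int(self.rng.integers(6, 25))
            ref_t = seq[off]
            alt_t = BASES[(BASES.index(ref_t) + int(self.rng.integers(1, 4))) % 4]
            alt_seq = seq[:off] + alt_t + seq[off + 1 :]
            a = longest_orf(seq)
            b = longest_orf(alt_seq)
            if (a.length if a else 0) != (b.length if b else 0):
                continue
            g = ts.genomic_positions[off]
            ref = self.genome[d.chrom][g]
            alt = alt_t if d.strand != "-" else revcomp(alt_t)
            if (d.chrom, g + 1) in {(r.chrom, r.pos) for r in self.rna_records}:
                continue
            second = None
            for cand in BASES:
                if cand in (ref, alt):
                    continue
                alt2_t = cand if d.strand != "-" else revcomp(cand)
                alt2_seq = seq[:off] + alt2_t + seq[off + 1 :]
                c = longest_orf(alt2_seq)
                if (a.length if a else 0) == (c.length if c else 0):
                    second = cand
                    break
            alts = [alt] + ([second] if second else [])
            return g + 1, ref, alts
        return None

    def _fill_expected_summaries(self) -> None:
        from collections import Counter

        from .concordance import venn_label

        venn_t = Counter({r: 0 for r in ("E", "R", "O", "ER", "EO", "RO", "ERO", "none")})
        venn_i = Counter({r: 0 for r in ("E", "R", "O", "ER", "EO", "RO", "ERO", "none")})
        for d, member in zip(self.designs, self._membership):
            label = venn_label(member)
            venn_t[label] += 1
            for _ in range(len(d.exon_lengths) - 1):
                venn_i[label] += 1
        self.truth.expected_venn_transcripts = dict(venn_t)
        self.truth.expected_venn_introns = dict(venn_i)
        self.truth.n_loci = len(self.designs)
        self.truth.loci_min2_exons = sum(1 for d in self.designs if len(d.exon_lengths) >= 2)
        self.truth.loci_min3_exons = sum(1 for d in self.designs if len(d.exon_lengths) >= 3)

        final = set()
        for d in self.designs:
            if d.role == "frag":
                final.add(d.model.transcript_id + "a+" + d.model.transcript_id + "b")
            else:
                final.add(d.model.transcript_id)
        self.truth.expected_final_transcripts = final
        self.truth.expected_excluded_transcripts = {
            t.transcript_id for t in self.noise_models
        }

        matrix = {
            sc: {"snp": 0, "insertion": 0, "deletion": 0}
            for sc in ("homozygous", "heterozygous", "unsupported")
        }
        group_class = {
            "planted_error": "homozygous",
            "het_decoy": "heterozygous",
            "unsupported_decoy": "unsupported",
        }
        mech = {"homopolymer_slips": 0, "intron_mimics": 0, "supported_extending_indels": 0}
        for p in self.truth.planted:
            sc = group_class.get(p.group)
            if sc is None:
                continue
            matrix[sc][p.variant_class] += 1
            if sc in ("homozygous", "heterozygous") and p.variant_class in ("insertion", "deletion"):
                mech["supported_extending_indels"] += 1
                if p.homopolymer_slip:
                    mech["homopolymer_slips"] += 1
                if p.intron_mimic:
                    mech["intron_mimics"] += 1
        self.truth.expected_error_matrix = matrix
        self.truth.expected_mechanism = mech

        counts = Counter()
        for r in self.rna_records:
            if self.truth.expected_filter_fail.get(r.record_id):
                continue
            from .variants import classify_genotype_position

            counts[classify_genotype_position(r)] += 1
        self.truth.expected_genotype_counts = dict(counts)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run every generator stage under one seed and return the dataset."""
    sim = Simulation(config)
    sim.generate_reference_and_truth()
    sim.fragment_transcripts()
    sim.simulate_reads()
    sim.simulate_variants_and_vcfs()
    return SimulatedDataset(
        config=config,
        genome=sim.genome,
        annotation_sets=sim.annotation_sets,
        annotation_beds=sim.annotation_beds,
        truth_transcripts=sim.gene_models,
        assembled_transcripts=sim.assembled,
        long_reads=sim.long_reads,
        alignments=sim.alignments,
        junctions=sim.junctions,
        rna_records=sim.rna_records,
        genomic_records=sim.genomic_records,
        known_records=sim.known_records,
        comparison_records=sim.comparison_records,
        evidence=sim.evidence,
        truth=sim.truth,
    )
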