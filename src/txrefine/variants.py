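"""Variant hard-filtering, genotype classification, indel normalization,
known-variant matching and cross-dataset support tabulation.

Hard filters follow the GATK-recommended rule set: a record fails when any
applicable metric rule triggers; a missing metric skips that rule (genotype
callers omit rank-sum metrics at homozygous sites, and failing those records
would discard exactly the reference-error candidates of interest).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .models import GenomeSequence, VariantRecord


@dataclass(frozen=True)
class HardFilterThresholds:
    """Per-class metric thresholds (fail direction noted in each name)."""

    snp_qd_min: float = 2.0  # QD < 2.0 fails
    snp_mq_min: float = 40.0  # MQ < 40.0 fails
    snp_fs_max: float = 60.0  # FS > 60.0 fails
    snp_haplotype_score_max: float = 13.0  # HaplotypeScore > 13.0 fails (genomic only)
    snp_mq_rank_sum_min: float = -12.5  # MQRankSum < -12.5 fails
    snp_read_pos_rank_sum_min: float = -8.0  # ReadPosRankSum < -8.0 fails
    indel_qd_min: float = 2.0  # QD < 2.0 fails
    indel_read_pos_rank_sum_min: float = -20.0  # ReadPosRankSum < -20.0 fails
    indel_fs_max: float = 200.0  # FS > 200.0 fails


DEFAULT_THRESHOLDS = HardFilterThresholds()


def failing_rules(
    record: VariantRecord,
    thresholds: HardFilterThresholds = DEFAULT_THRESHOLDS,
    use_haplotype_score: bool = False,
) -> List[str]:
    """Names of every hard-filter rule the record triggers (strict inequalities)."""
    cls = record.variant_class
    metrics = record.info_metrics
    reasons: List[str] = []

    def check(name: str, value_key: str, bound: float, direction: str) -> None:
        value = metrics.get(value_key)
        if value is None:
            return  # absent metric: rule skipped
        if (direction == "lt" and value < bound) or (direction == "gt" and value > bound):
            reasons.append(name)

    if cls == "snp":
        check("QD", "QD", thresholds.snp_qd_min, "lt")
        check("MQ", "MQ", thresholds.snp_mq_min, "lt")
        check("FS", "FS", thresholds.snp_fs_max, "gt")
        if use_haplotype_score:
            check("HaplotypeScore", "HaplotypeScore", thresholds.snp_haplotype_score_max, "gt")
        check("MQRankSum", "MQRankSum", thresholds.snp_mq_rank_sum_min, "lt")
        check("ReadPosRankSum", "ReadPosRankSum", thresholds.snp_read_pos_rank_sum_min, "lt")
    elif cls in ("insertion", "deletion", "mixed"):
        # mixed records (ref and alt both multi-base) run under the indel rules
        check("QD", "QD", thresholds.indel_qd_min, "lt")
        check("ReadPosRankSum", "ReadPosRankSum", thresholds.indel_read_pos_rank_sum_min, "lt")
        check("FS", "FS", thresholds.indel_fs_max, "gt")
    else:
        raise ValueError(f"unknown variant class {cls!r}")
    return reasons


def apply_hard_filters(
    records: Sequence[VariantRecord],
    thresholds: HardFilterThresholds = DEFAULT_THRESHOLDS,
    use_haplotype_score: bool = False,
) -> Tuple[List[VariantRecord], List[Tuple[VariantRecord, List[str]]]]:
    """Partition records into (passing, failing-with-reasons)."""
    passing: List[VariantRecord] = []
    failing: List[Tuple[VariantRecord, List[str]]] = []
    for rec in records:
        reasons = failing_rules(rec, thresholds, use_haplotype_score)
        if reasons:
            failing.append((rec, reasons))
        else:
            passing.append(rec)
    return passing, failing


GENOTYPE_CATEGORIES = (
    "homozygous_alt",
    "mixed_allele",
    "other",
    "missing",
    "homozygous_ref",
)


def classify_genotype_position(record: VariantRecord) -> str:
    """Genotype category derived solely from the GT field.

    Identical non-reference alleles -> homozygous_alt; one reference plus one
    alternate -> mixed_allele; two different non-reference alleles -> other;
    no call -> missing.  GT 0/0 (possible in genomic calls made at RNA-derived
    positions) is reported as homozygous_ref.
    """
    gt = record.genotype
    if gt is None:
        return "missing"
    a, b = gt
    if a == b:
        return "homozygous_ref" if a == 0 else "homozygous_alt"
    if 0 in (a, b):
        return "mixed_allele"
    return "other"


def normalize_allele(
    genome: GenomeSequence, chrom: str, pos: int, ref: str, alt: str
) -> Tuple[int, str, str]:
    """Canonical (pos, ref, alt): trimmed and left-aligned against the genome.

    Standard indel left-alignment: shared trailing bases are dropped
    (prepending the preceding genomic base when an allele would empty),
    then shared leading bases are dropped.  Idempotent; raises ValueError on
    a reference mismatch.
    """
    chrom_seq = genome.get(chrom)
    if chrom_seq is None:
        raise ValueError(f"chromosome {chrom!r} not in genome")
    if chrom_seq[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos} (expected {ref!r})"
        )
    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref = ref[:-1]
            alt = alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise ValueError(f"cannot left-align allele at {chrom}:1")
                pos -= 1
                base = chrom_seq[pos - 1]
                ref = base + ref
                alt = base + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(record: VariantRecord, genome: GenomeSequence) -> VariantRecord:
    """Record with every allele in canonical form.

    Bi-allelic records are fully normalized.  For multi-allelic records each
    canonical allele can land at a different position, so the record is
    returned unchanged (per-allele analyses normalize through
    :func:`normalize_allele`).
    """
    if len(record.alt_alleles) != 1:
        chrom_seq = genome.get(record.chrom, "")
        if chrom_seq[record.pos - 1 : record.pos - 1 + len(record.ref_allele)] != record.ref_allele:
            raise ValueError(f"reference mismatch at {record.chrom}:{record.pos}")
        return record
    pos, ref, alt = normalize_allele(
        genome, record.chrom, record.pos, record.ref_allele, record.alt_alleles[0]
    )
    return VariantRecord(
        chrom=record.chrom,
        pos=pos,
        ref_allele=ref,
        alt_alleles=[alt],
        genotype=record.genotype,
        info_metrics=dict(record.info_metrics),
        allele_depths=list(record.allele_depths) if record.allele_depths else None,
        record_id=record.record_id,
    )


AlleleKey = Tuple[str, int, str, str]


def allele_keys(
    record: VariantRecord, genome: GenomeSequence, by: str = "position_allele"
) -> List[AlleleKey]:
    """Normalized comparison keys, one per ALT allele."""
    keys = []
    for alt in record.alt_alleles:
        pos, ref, norm_alt = normalize_allele(
            genome, record.chrom, record.pos, record.ref_allele, alt
        )
        if by == "position_allele":
            keys.append((record.chrom, pos, ref, norm_alt))
        elif by == "position":
            keys.append((record.chrom, pos, "", ""))
        else:
            raise ValueError(f"unknown matching mode {by!r}")
    return keys


def match_known_variants(
    records: Sequence[VariantRecord],
    known_set: Sequence[VariantRecord],
    genome: GenomeSequence,
    by: str = "position_allele",
) -> Tuple[List[bool], float]:
    """Per-record known flag (any allele matches) and the matched fraction."""
    known: Set[AlleleKey] = set()
    for rec in known_set:
        known.update(allele_keys(rec, genome, by))
    flags = []
    for rec in records:
        flags.append(any(k in known for k in allele_keys(rec, genome, by)))
    fraction = sum(flags) / len(flags) if flags else 0.0
    return flags, fraction


@dataclass
class SupportTable:
    """Per variant class: counts of variants found in exactly k comparison sets.

    Bin 0 is the "not validated" column.  Row sums equal class totals.
    """

    n_sets: int
    bins: Dict[str, Dict[int, int]] = field(default_factory=dict)

    def to_dict(self) -> Dict:
        return {
            "n_sets": self.n_sets,
            "bins": {cls: {str(k): v for k, v in sorted(b.items())} for cls, b in sorted(self.bins.items())},
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "SupportTable":
        return cls(
            n_sets=d["n_sets"],
            bins={c: {int(k): v for k, v in b.items()} for c, b in d["bins"].items()},
        )

    def class_total(self, variant_class: str) -> int:
        return sum(self.bins.get(variant_class, {}).values())


def tabulate_dataset_support(
    records: Sequence[VariantRecord],
    comparison_sets: Sequence[Sequence[VariantRecord]],
    genome: GenomeSequence,
    extra_set: Optional[Sequence[VariantRecord]] = None,
    by: str = "position_allele",
) -> SupportTable:
    """Bin each variant allele by how many comparison datasets contain it.

    ``extra_set`` (e.g. the reference individual's own resequencing calls)
    extends the dataset count by one, mirroring the "including the reference
    animal" table variant.  Invariant to comparison-set ordering.
    """
    sets: List[Set[AlleleKey]] = []
    all_sets = list(comparison_sets) + ([extra_set] if extra_set is not None else [])
    for cmp_records in all_sets:
        keys: Set[AlleleKey] = set()
        for rec in cmp_records:
            keys.update(allele_keys(rec, genome, by))
        sets.append(keys)
    table = SupportTable(n_sets=len(sets), bins={})
    for rec in records:
        for i, alt in enumerate(rec.alt_alleles):
            key = allele_keys(rec, genome, by)[i]
            k = sum(1 for s in sets if key in s)
            cls = rec.allele_class(i)
            table.bins.setdefault(cls, {})
            table.bins[cls][k] = table.bins[cls].get(k, 0) + 1
    return table
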