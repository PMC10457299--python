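"""Site-quality hard filters and bulk-genotyping criteria for QTL-seq input.

Two per-record predicates produce the analysis-ready SNP set:

1. GATK-style hard filter on site annotations — a record is removed iff any
   *present* annotation violates its strict inequality
   (QD < 2.0, FS > 60.0, MQ < 20.0, MQRankSum < -12.5, ReadPosRankSum < -8.0);
   absent annotations never cause removal.
2. Bulk genotyping criteria — sequencing depth of every bulk and parent at
   least ``min_depth`` (default 5), both parents homozygous with different
   genotypes, and the reference-role parent matching the reference genome
   (genotype 0/0).

Both filters are pure per-record predicates, so their composition is
order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from cyvcf2 import VCF

from bulkscan.simbulk import (
    SAMPLE_BULK_HIGH,
    SAMPLE_BULK_LOW,
    SAMPLE_PARENT_BLACK,
    SAMPLE_PARENT_YELLOW,
)

log = logging.getLogger(__name__)

ROLE_PARENT_REF = "parent_ref"
ROLE_PARENT_ALT = "parent_alt"
ROLE_BULK_HIGH = "bulk_high"
ROLE_BULK_LOW = "bulk_low"
ROLES = (ROLE_PARENT_REF, ROLE_PARENT_ALT, ROLE_BULK_HIGH, ROLE_BULK_LOW)

#: sample-name mapping matching simbulk's VCF output
DEFAULT_ROLE_MAP = {
    ROLE_PARENT_REF: SAMPLE_PARENT_BLACK,
    ROLE_PARENT_ALT: SAMPLE_PARENT_YELLOW,
    ROLE_BULK_HIGH: SAMPLE_BULK_HIGH,
    ROLE_BULK_LOW: SAMPLE_BULK_LOW,
}

#: thresholds of the hard filter; each rule is (key, kind) with kind "lt"
#: meaning "remove if value < threshold" and "gt" "remove if value > threshold"
DEFAULT_QUALITY_THRESHOLDS = {
    "QD": ("lt", 2.0),
    "FS": ("gt", 60.0),
    "MQ": ("lt", 20.0),
    "MQRankSum": ("lt", -12.5),
    "ReadPosRankSum": ("lt", -8.0),
}


@dataclass(frozen=True)
class SampleCall:
    """One sample's call at a site: genotype, allele depths, total depth."""

    gt: tuple[int, int] | None  # allele indices, None = missing
    ad: tuple[int, int] | None  # (ref, alt) read counts
    dp: int | None

    @property
    def depth(self) -> int | None:
        """Sequencing depth: DP when reported, else the AD sum."""
        if self.dp is not None:
            return self.dp
        if self.ad is not None:
            return self.ad[0] + self.ad[1]
        return None

    @property
    def is_homozygous(self) -> bool:
        return self.gt is not None and self.gt[0] == self.gt[1]


@dataclass
class VariantRecord:
    """One bi-allelic site with per-role calls and site-quality annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    calls: dict[str, SampleCall]
    annotations: dict[str, float | None] = field(default_factory=dict)

    @property
    def variant_class(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNP"
        if len(self.alt) > len(self.ref):
            return "insertion"
        if len(self.alt) < len(self.ref):
            return "deletion"
        return "SNP"  # equal-length multi-nucleotide substitution, treated as SNP-like


@dataclass
class FilterOutcome:
    """Result of applying a filter: kept iff no rule failed."""

    reasons: list[str] = field(default_factory=list)

    @property
    def kept(self) -> bool:
        return not self.reasons


def _parse_gt(gt_entry) -> tuple[int, int] | None:
    # cyvcf2 genotypes entry: [a0, a1, phased]; -1 marks a missing allele
    a = gt_entry[0], gt_entry[1]
    if a[0] < 0 or a[1] < 0:
        return None
    return int(a[0]), int(a[1])


def read_variants(
    vcf_path: str, role_map: dict[str, str] | None = None
) -> Iterator[VariantRecord]:
    """Stream bi-allelic records from a VCF, keyed by sample role.

    ``role_map`` maps the four roles (parent_ref, parent_alt, bulk_high,
    bulk_low) to sample names in the file; the default matches simbulk
    output.  Multi-allelic records are dropped (their count is logged).
    """
    role_map = role_map or DEFAULT_ROLE_MAP
    vcf = VCF(vcf_path, gts012=False)
    samples = list(vcf.samples)
    idx = {}
    for role in ROLES:
        name = role_map.get(role)
        if name is None or name not in samples:
            raise ValueError(f"role {role!r} not mapped to a sample in {vcf_path}")
        idx[role] = samples.index(name)
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ad = v.format("AD")
        dp = v.format("DP")
        gts = v.genotypes
        calls = {}
        for role, i in idx.items():
            ad_i = None
            if ad is not None:
                pair = ad[i]
                if len(pair) >= 2 and pair[0] >= 0 and pair[1] >= 0:
                    ad_i = (int(pair[0]), int(pair[1]))
            dp_i = None
            if dp is not None and dp[i][0] >= 0:
                dp_i = int(dp[i][0])
            calls[role] = SampleCall(gt=_parse_gt(gts[i]), ad=ad_i, dp=dp_i)
        annotations = {}
        for key in DEFAULT_QUALITY_THRESHOLDS:
            val = v.INFO.get(key)
            annotations[key] = float(val) if val is not None else None
        yield VariantRecord(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alt=v.ALT[0],
            calls=calls,
            annotations=annotations,
        )
    if n_multi:
        log.info("dropped %d multi-allelic records", n_multi)
    vcf.close()


def apply_site_quality_filter(
    rec: VariantRecord, thresholds: dict[str, tuple[str, float]] | None = None
) -> FilterOutcome:
    """Hard filter on site annotations; strict inequalities, boundary passes.

    Absent annotations are legal (rank-sum statistics are undefined for
    sites where all samples agree) and never cause removal.
    """
    thresholds = thresholds or DEFAULT_QUALITY_THRESHOLDS
    outcome = FilterOutcome()
    for key, (kind, cut) in thresholds.items():
        val = rec.annotations.get(key)
        if val is None:
            continue
        if (kind == "lt" and val < cut) or (kind == "gt" and val > cut):
            outcome.reasons.append(key)
    return outcome


def apply_bulk_genotyping_filter(rec: VariantRecord, min_depth: int = 5) -> FilterOutcome:
    """The three bulk-genotyping criteria.

    Kept iff depth >= min_depth in all four samples, both parents are
    homozygous with different genotypes, and the reference-role parent is
    homozygous reference.
    """
    outcome = FilterOutcome()
    for role in ROLES:
        depth = rec.calls[role].depth
        if depth is None or depth < min_depth:
            outcome.reasons.append("depth")
            break
    p_ref = rec.calls[ROLE_PARENT_REF]
    p_alt = rec.calls[ROLE_PARENT_ALT]
    if p_ref.gt is None or p_alt.gt is None:
        outcome.reasons.append("parent_missing")
        return outcome
    if not (p_ref.is_homozygous and p_alt.is_homozygous):
        outcome.reasons.append("parent_heterozygous")
    elif p_ref.gt == p_alt.gt:
        outcome.reasons.append("parents_identical")
    if p_ref.is_homozygous and p_ref.gt != (0, 0):
        outcome.reasons.append("reference_mismatch")
    return outcome


@dataclass
class FilterSummary:
    """Per-rule removal tallies; every removal carries at least one reason."""

    n_input: int = 0
    n_kept: int = 0
    reason_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept

    def to_frame(self):
        import pandas as pd

        rows = [{"rule": k, "removed": v} for k, v in sorted(self.reason_counts.items())]
        return pd.DataFrame(rows, columns=["rule", "removed"])


def filter_variants(
    records: Iterable[VariantRecord],
    thresholds: dict[str, tuple[str, float]] | None = None,
    min_depth: int = 5,
    summary: FilterSummary | None = None,
) -> Iterator[tuple[VariantRecord, FilterOutcome]]:
    """Apply both filters to a record stream, yielding (record, outcome).

    Pass a :class:`FilterSummary` to collect counts while streaming.
    """
    for rec in records:
        outcome = apply_site_quality_filter(rec, thresholds)
        outcome.reasons.extend(apply_bulk_genotyping_filter(rec, min_depth).reasons)
        if summary is not None:
            summary.n_input += 1
            if outcome.kept:
                summary.n_kept += 1
            for reason in outcome.reasons:
                summary.reason_counts[reason] = summary.reason_counts.get(reason, 0) + 1
        yield rec, outcome


def kept_variants(
    records: Iterable[VariantRecord],
    thresholds: dict[str, tuple[str, float]] | None = None,
    min_depth: int = 5,
    summary: FilterSummary | None = None,
) -> Iterator[VariantRecord]:
    """Convenience stream of only the records passing both filters."""
    for rec, outcome in filter_variants(records, thresholds, min_depth, summary):
        if outcome.kept:
            yield rec


def write_filtered_vcf(
    vcf_in: str,
    vcf_out: str,
    role_map: dict[str, str] | None = None,
    thresholds: dict[str, tuple[str, float]] | None = None,
    min_depth: int = 5,
) -> FilterSummary:
    """Re-emit a VCF with the FILTER column set to PASS or the failed rules."""
    role_map = role_map or DEFAULT_ROLE_MAP
    summary = FilterSummary()
    outcomes = {
        (rec.chrom, rec.pos): outcome
        for rec, outcome in filter_variants(
            read_variants(vcf_in, role_map), thresholds, min_depth, summary
        )
    }
    with open(vcf_in) as fin, open(vcf_out, "w") as fout:
        wrote_filter_header = False
        for line in fin:
            if line.startswith("##"):
                fout.write(line)
                continue
            if line.startswith("#CHROM"):
                if not wrote_filter_header:
                    fout.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
                    wrote_filter_header = True
                fout.write(line)
                continue
            fields = line.rstrip("\n").split("\t")
            key = (fields[0], int(fields[1]))
            outcome = outcomes.get(key)
            if outcome is None:  # multi-allelic, dropped entirely
                continue
            fields[6] = "PASS" if outcome.kept else ";".join(outcome.reasons)
            fout.write("\t".join(fields) + "\n")
    return summary
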