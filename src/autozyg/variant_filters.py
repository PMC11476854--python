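"""SNV retention logic of the case-study pipeline.

The chain mirrors a GATK post-calling workflow: SNP-only selection,
hard filtering on calling annotations (with a depth-percentile rule),
exclusion of known variants, selection of variants private to the
proband, and a partition of the survivors by genomic compartment
(autosome / X / MT).

Semantics follow the tools the workflow emulates: every inequality is
strict exactly as written in the filter expression (a value sitting on
the threshold passes); a record lacking an annotation passes that
filter, as GATK's VariantFiltration treats missing annotations as
non-failing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .vcf_io import (CompartmentNaming, DEFAULT_NAMING, MergedVariantTable,
                     VariantRecord)


@dataclass(frozen=True)
class HardFilterThresholds:
    """Hard-filter thresholds on variant-calling annotations.

    Defaults are the values used for the case study: QD < 2.0,
    FS > 60.0, MQ < 56.0, SOR > 3.0, MQRankSum < -12.5,
    ReadPosRankSum < -8.0, plus a read-depth rule at the 75th
    percentile of site DP.
    """

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 56.0
    sor_max: float = 3.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    dp_quantile: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.dp_quantile < 1.0:
            raise ValueError("dp_quantile must be strictly between 0 and 1")


@dataclass
class FilterVerdict:
    """Outcome of the hard filters for one record."""

    record: VariantRecord
    reasons: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


def dp_quantile_threshold(dp_values: Sequence[float], q: float) -> float:
    """Nearest-rank q-quantile: the sorted value at 1-based position ceil(q*n).

    This is the unambiguous, interpolation-free percentile definition, so
    the depth threshold is always an observed DP value.
    """
    if len(dp_values) == 0:
        raise ValueError("dp_values must be non-empty")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be strictly between 0 and 1")
    ordered = sorted(dp_values)
    return ordered[math.ceil(q * len(ordered)) - 1]


def apply_hard_filters(table: MergedVariantTable,
                       thresholds: HardFilterThresholds = HardFilterThresholds(),
                       *,
                       dp_rule: bool = True,
                       dp_direction: str = "below") -> list:
    """Evaluate the hard filters for every record.

    The DP threshold is the ``thresholds.dp_quantile`` nearest-rank
    percentile of the DP values of *this* table, so it must be computed
    before any downstream subsetting. ``dp_direction="below"`` discards
    records with DP strictly below the threshold (the case-study rule,
    which keeps only the deepest quartile of sites); ``"above"`` inverts
    the rule for the conventional high-depth cut.
    """
    if dp_direction not in ("below", "above"):
        raise ValueError("dp_direction must be 'below' or 'above'")
    dp_threshold = None
    if dp_rule:
        dps = [r.annotations["DP"] for r in table.records if "DP" in r.annotations]
        if dps:
            dp_threshold = dp_quantile_threshold(dps, thresholds.dp_quantile)

    verdicts = []
    t = thresholds
    for rec in table.records:
        ann = rec.annotations
        reasons = []
        if "QD" in ann and ann["QD"] < t.qd_min:
            reasons.append("QD")
        if "FS" in ann and ann["FS"] > t.fs_max:
            reasons.append("FS")
        if "MQ" in ann and ann["MQ"] < t.mq_min:
            reasons.append("MQ")
        if "SOR" in ann and ann["SOR"] > t.sor_max:
            reasons.append("SOR")
        if "MQRankSum" in ann and ann["MQRankSum"] < t.mqranksum_min:
            reasons.append("MQRankSum")
        if "ReadPosRankSum" in ann and ann["ReadPosRankSum"] < t.readposranksum_min:
            reasons.append("ReadPosRankSum")
        if dp_threshold is not None and "DP" in ann:
            dp = ann["DP"]
            if (dp < dp_threshold) if dp_direction == "below" else (dp > dp_threshold):
                reasons.append("DP")
        verdicts.append(FilterVerdict(record=rec, reasons=reasons))
    return verdicts


def passing_table(table: MergedVariantTable, verdicts: Iterable[FilterVerdict]
                  ) -> MergedVariantTable:
    """Subset the table to the records whose verdict passed."""
    kept = [v.record for v in verdicts if v.passed]
    return MergedVariantTable(samples=list(table.samples), records=kept)


def select_snps(table: MergedVariantTable) -> MergedVariantTable:
    """Retain records whose ref and every alt are single nucleotides.

    A record with any non-SNV allele is dropped whole, matching
    record-level SNP selection semantics.
    """
    kept = [r for r in table.records if r.is_snv()]
    return MergedVariantTable(samples=list(table.samples), records=kept)


def exclude_known(table: MergedVariantTable, known: set,
                  *, match: str = "allele") -> MergedVariantTable:
    """Remove records present in a known-variant set (e.g. dbSNP export).

    ``match="allele"`` (default) requires (chrom, pos, ref, alt) identity;
    a multi-allelic record is removed only if *every* alt matches a known
    entry, so novel alleles at known sites survive. ``match="position"``
    removes on (chrom, pos) membership alone.
    """
    if match not in ("allele", "position"):
        raise ValueError("match must be 'allele' or 'position'")
    kept = []
    for rec in table.records:
        if match == "position":
            remove = (rec.chromosome, rec.position) in known
        else:
            remove = all((rec.chromosome, rec.position, rec.ref_allele, alt) in known
                         for alt in rec.alt_alleles)
        if not remove:
            kept.append(rec)
    return MergedVariantTable(samples=list(table.samples), records=kept)


def proband_unique(table: MergedVariantTable, proband_id: str
                   ) -> MergedVariantTable:
    """Retain variants private to the proband.

    A record is retained when every sample has a non-missing call, the
    proband carries at least one alt allele, and some proband alt allele
    is absent — even in heterozygosity — from every other sample.
    Haploid records apply the same rule to single-allele calls.
    """
    if proband_id not in table.samples:
        raise ValueError(f"proband {proband_id!r} not among samples {table.samples}")
    if len(table.samples) < 2:
        raise ValueError("need at least one non-proband sample")
    controls = [s for s in table.samples if s != proband_id]
    kept = []
    for rec in table.records:
        gts = rec.genotypes
        if any(gts[s] is None for s in table.samples):
            continue
        proband_alts = set(gts[proband_id]) - {0}
        if not proband_alts:
            continue
        control_alleles = set()
        for s in controls:
            control_alleles.update(gts[s])
        if proband_alts - control_alleles:
            kept.append(rec)
    return MergedVariantTable(samples=list(table.samples), records=kept)


def partition_by_compartment(table: MergedVariantTable,
                             naming: CompartmentNaming = DEFAULT_NAMING) -> dict:
    """Count records per genomic compartment {autosome, X, MT}."""
    counts = {"autosome": 0, "X": 0, "MT": 0}
    for rec in table.records:
        counts[naming.compartment_of(rec.chromosome)] += 1
    return counts
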