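"""End-to-end orchestration of the case-study analysis.

``run_pipeline`` executes the post-calling workflow on a merged VCF (real
or simulated): SNP selection, hard filtering with the depth-percentile
rule, then two branches — (a) known-variant exclusion, proband-unique
selection and compartment partitioning; (b) per-sample ROH detection on
the hard-filtered SNP backdrop, summary statistics, F_ROH and pedigree
expectations, gene overlap and keyword triage. Every intermediate is
written as a tab-separated file and a survivor-count ledger is logged.

ROH runs on the hard-filtered set, not after known-variant exclusion:
removing known (common) SNPs would delete exactly the polymorphic
backdrop that homozygosity scanning needs, while the unique-variant
branch needs it removed.

``mosaic_fraction`` is the small clinical helper for karyotype mosaicism
(percentage plus exact Clopper-Pearson binomial interval).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from . import annotate_overlap, inbreeding, roh, variant_filters, vcf_io
from . import synthetic_data

logger = logging.getLogger("autozyg")


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of vcf_path / sim must be set."""

    vcf_path: Optional[str] = None
    sim: Optional[synthetic_data.SimulationConfig] = None
    proband_id: str = "proband"
    known_path: Optional[str] = None
    gene_bed_path: Optional[str] = None
    enrichment_path: Optional[str] = None
    pedigree_path: Optional[str] = None
    thresholds: variant_filters.HardFilterThresholds = field(
        default_factory=variant_filters.HardFilterThresholds)
    dp_rule: bool = True
    dp_direction: str = "below"
    roh_params: roh.RohParams = field(default_factory=roh.RohParams)
    autosome_kb: Optional[float] = None  # default: simulated total or CanFam6
    keywords: tuple = annotate_overlap.DEFAULT_KEYWORDS
    out_dir: str = "pipeline_out"
    seed: int = 0
    log_level: int = logging.INFO

    def __post_init__(self) -> None:
        if (self.vcf_path is None) == (self.sim is None):
            raise ValueError("set exactly one of vcf_path / sim")


@dataclass
class PipelineReport:
    config: PipelineConfig
    stage_counts: dict
    partition: dict
    unique_table: vcf_io.MergedVariantTable
    segments: dict            # sample -> list[ROHSegment]
    summaries: dict           # sample -> RohSummary
    inbreeding_rows: list     # (sample, f_roh, f_expected, baseline)
    overlap_union: list
    triage_counts: dict
    injected_truth: list


def _read_known(path: str) -> set:
    """Known-variant file: VCF or 4-column TSV (chrom, pos, ref, alt)."""
    known = set()
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        table = vcf_io.read_merged_vcf(path)
        for rec in table.records:
            for alt in rec.alt_alleles:
                known.add((rec.chromosome, rec.position, rec.ref_allele, alt))
        return known
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise vcf_io.FormatError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            known.add((fields[0], int(fields[1]), fields[2], fields[3]))
    return known


def _write_segments(path, segments_by_sample) -> None:
    rows = []
    for sample in segments_by_sample:
        for s in segments_by_sample[sample]:
            rows.append((s.sample_id, s.chromosome, s.start_bp, s.end_bp,
                         s.n_snps, f"{s.length_kb:.3f}"))
    vcf_io.write_tsv(path, ("sample", "chrom", "start_bp", "end_bp",
                            "n_snps", "length_kb"), rows)


def _simulate_inputs(config: PipelineConfig, out: Path):
    sim = synthetic_data.simulate_dataset(config.sim)
    rng = np.random.default_rng(config.sim.seed + 1)
    table = synthetic_data.to_variant_table(sim, rng=rng)
    table, injected = synthetic_data.inject_unique_variants(
        table, config.proband_id, rng,
        count=config.sim.de_novo_count, split=config.sim.de_novo_split,
        cluster=config.sim.de_novo_cluster)
    table, _labels = synthetic_data.attach_quality_annotations(
        table, config.sim.annotation_fail_fraction, rng)
    vcf_io.write_vcf(table, out / "simulated.vcf", contig_lengths={
        c.name: c.length_bp for c in sim.marker_map.chromosomes})
    vcf_io.write_pedigree(sim.pedigree, out / "pedigree.ped")
    vcf_io.write_tsv(out / "truth_injected.tsv",
                     ("chrom", "pos", "ref", "alt"), injected)
    vcf_io.write_tsv(out / "truth_autozygous_segments.tsv",
                     ("sample", "chrom", "start_bp", "end_bp"),
                     [(s, *seg) for s in sim.samples
                      for seg in sim.true_autozygous_segments(s)])
    return sim, table, injected


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> PipelineReport:
    counts = {}
    sim = None
    injected: list = []
    if config.sim is not None:
        sim, table, injected = _simulate_inputs(config, out)
        autosome_kb = config.autosome_kb or sim.marker_map.total_autosome_kb
        pedigree = sim.pedigree
    else:
        table = vcf_io.read_merged_vcf(config.vcf_path)
        autosome_kb = config.autosome_kb or inbreeding.AUTOSOME_KB_CANFAM6
        pedigree = (vcf_io.read_pedigree(config.pedigree_path)
                    if config.pedigree_path else None)
    counts["input"] = len(table)
    logger.info("input records: %d (%d samples)", len(table), len(table.samples))

    table = variant_filters.select_snps(table)
    counts["snp_only"] = len(table)
    logger.info("after SNP-only selection: %d", len(table))

    verdicts = variant_filters.apply_hard_filters(
        table, config.thresholds, dp_rule=config.dp_rule,
        dp_direction=config.dp_direction)
    filtered = variant_filters.passing_table(table, verdicts)
    counts["hard_filtered"] = len(filtered)
    logger.info("after hard filters (+DP rule): %d", len(filtered))
    vcf_io.write_tsv(out / "filter_ledger.tsv", ("chrom", "pos", "passed",
                                                 "reasons"),
                     [(v.record.chromosome, v.record.position,
                       int(v.passed), ",".join(v.reasons)) for v in verdicts])

    # branch (a): proband-unique variants
    known = _read_known(config.known_path) if config.known_path else set()
    unique = variant_filters.exclude_known(filtered, known)
    counts["known_excluded"] = len(unique)
    unique = variant_filters.proband_unique(unique, config.proband_id)
    counts["proband_unique"] = len(unique)
    logger.info("proband-unique SNVs: %d", len(unique))
    partition = variant_filters.partition_by_compartment(unique)
    vcf_io.write_tsv(out / "unique_variants.tsv",
                     ("chrom", "pos", "ref", "alts", "proband_gt"),
                     [(r.chromosome, r.position, r.ref_allele,
                       ",".join(r.alt_alleles),
                       "/".join(map(str, r.genotypes[config.proband_id] or ())))
                      for r in unique.records])

    # branch (b): ROH on the hard-filtered SNP backdrop
    segments, summaries = {}, {}
    for sample in table.samples:
        codes = roh.genotype_codes(filtered, sample)
        segs = roh.detect_roh(sample, codes, config.roh_params)
        segments[sample] = segs
        summaries[sample] = roh.summarize_roh(segs, autosome_kb, sample_id=sample)
        logger.info("ROH %s: nseg=%d total_kb=%.1f f_roh=%.3f", sample,
                    summaries[sample].nseg, summaries[sample].total_kb,
                    summaries[sample].f_roh)
    _write_segments(out / "roh_segments.tsv", segments)
    vcf_io.write_tsv(out / "roh_summary.tsv",
                     ("SAMPLE", "NSEG", "KB", "KBAVG", "F_ROH"),
                     [(s.sample_id, s.nseg, f"{s.total_kb:.1f}",
                       f"{s.kb_avg:.2f}", f"{s.f_roh:.3f}")
                      for s in summaries.values()])

    controls = [summaries[s] for s in table.samples if s != config.proband_id]
    baseline = inbreeding.baseline_from_controls(controls) if controls else None
    inbreeding_rows = []
    for sample in table.samples:
        expected = None
        if pedigree is not None and sample in pedigree:
            ind = pedigree[sample]
            if ind.father is not None and ind.mother is not None:
                expected = inbreeding.expected_inbreeding(pedigree, sample)
        inbreeding_rows.append((sample, summaries[sample].f_roh, expected,
                                baseline))
    if baseline is not None:
        logger.info("control baseline F_ROH %.3f -> sib-mating expectation %.3f",
                    baseline, inbreeding.expected_sib_f(baseline))
    vcf_io.write_tsv(out / "inbreeding.tsv",
                     ("sample", "f_roh", "f_expected", "baseline"),
                     [(s, f"{f:.4f}",
                       "NA" if e is None else f"{e:.4f}",
                       "NA" if b is None else f"{b:.4f}")
                      for s, f, e, b in inbreeding_rows])

    overlap_union: list = []
    if config.gene_bed_path:
        genes = vcf_io.read_gene_bed(config.gene_bed_path)
        _per_seg, overlap_union = annotate_overlap.overlap_genes(
            segments[config.proband_id], genes)
        vcf_io.write_tsv(out / "overlap_genes.tsv", ("gene",),
                         [(g,) for g in overlap_union])
        logger.info("genes in proband ROH: %d", len(overlap_union))

    triage_counts: dict = {}
    if config.enrichment_path:
        rows = annotate_overlap.read_enrichment_table(config.enrichment_path)
        retained, triage_counts, tri_genes = annotate_overlap.keyword_triage(
            rows, config.keywords)
        annotate_overlap.write_enrichment_table(retained, out / "triage.tsv")
        vcf_io.write_tsv(out / "triage_genes.tsv", ("gene",),
                         [(g,) for g in tri_genes])
        logger.info("triage kept %d rows across %s", len(retained), triage_counts)

    return PipelineReport(
        config=config, stage_counts=counts, partition=partition,
        unique_table=unique, segments=segments, summaries=summaries,
        inbreeding_rows=inbreeding_rows, overlap_union=overlap_union,
        triage_counts=triage_counts, injected_truth=injected)


def mosaic_fraction(n_abnormal: int, n_total: int, confidence: float = 0.95
                    ) -> Tuple[int, Tuple[float, float]]:
    """Mosaicism percentage with an exact (Clopper-Pearson) binomial CI.

    Returns the percentage rounded to the nearest integer and the
    confidence interval endpoints as fractions in [0, 1].
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_abnormal <= n_total:
        raise ValueError("need 0 <= n_abnormal <= n_total")
    alpha = 1.0 - confidence
    k, n = n_abnormal, n_total
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return int(inbreeding.round_half_up(100.0 * k / n, 0)), (lo, hi)
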