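"""Readers and writers for the file formats the pipeline touches.

Multi-sample VCF goes through pysam/htslib; BED4 gene annotations,
pedigree files and tab-separated reports are plain text.

Coordinate conventions: VCF positions are 1-based (kept as such in
:class:`VariantRecord`); BED intervals are 0-based half-open (kept as such
in :class:`GeneInterval`). All internal interval arithmetic is done on
1-based inclusive coordinates; the converters live at the module
boundaries (see :func:`autozyg.annotate_overlap.overlap_genes`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pysam

#: Site-level INFO annotations the pipeline knows about. DP is emitted as an
#: integer (as variant callers do); the rest as floats.
ANNOTATION_KEYS = ("DP", "QD", "FS", "MQ", "SOR", "MQRankSum", "ReadPosRankSum")

_NUCLEOTIDES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violated its format contract (message names the offending line)."""


@dataclass(frozen=True)
class CompartmentNaming:
    """Maps chromosome names onto the {autosome, X, MT} compartments.

    Anything not recognized as X or MT counts as an autosome, so the
    package stays genome-build agnostic.
    """

    x_names: frozenset = frozenset({"X", "chrX"})
    mt_names: frozenset = frozenset({"MT", "M", "chrM", "chrMT"})

    def compartment_of(self, chromosome: str) -> str:
        if chromosome in self.x_names:
            return "X"
        if chromosome in self.mt_names:
            return "MT"
        return "autosome"


DEFAULT_NAMING = CompartmentNaming()

#: A diploid genotype is a 2-tuple of allele indices, a haploid one (MT) a
#: 1-tuple; a missing call is None. Allele index 0 is the ref allele.
Genotype = Optional[tuple]


@dataclass
class VariantRecord:
    """One multi-sample SNV/indel row of a merged, genotyped VCF."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_alleles: tuple
    annotations: dict = field(default_factory=dict)
    genotypes: dict = field(default_factory=dict)  # sample -> Genotype

    def validate(self) -> None:
        if not self.ref_allele or not set(self.ref_allele) <= _NUCLEOTIDES:
            raise ValueError(f"bad ref allele {self.ref_allele!r} at "
                             f"{self.chromosome}:{self.position}")
        if not self.alt_alleles:
            raise ValueError(f"no alt alleles at {self.chromosome}:{self.position}")
        for alt in self.alt_alleles:
            if not alt or not set(alt) <= _NUCLEOTIDES:
                raise ValueError(f"bad alt allele {alt!r} at "
                                 f"{self.chromosome}:{self.position}")
        n_alleles = 1 + len(self.alt_alleles)
        for sample, gt in self.genotypes.items():
            if gt is None:
                continue
            for a in gt:
                if not (0 <= a < n_alleles):
                    raise ValueError(
                        f"allele index {a} out of range for sample {sample} at "
                        f"{self.chromosome}:{self.position}")

    def is_snv(self) -> bool:
        """True when ref and every alt are single nucleotides."""
        return len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles)


@dataclass
class MergedVariantTable:
    """In-memory form of a merged multi-sample VCF.

    Records are kept sorted by (chromosome, position) where chromosome
    order is the order of first appearance (mirroring a reference-sorted
    VCF); every record carries one genotype slot per sample.
    """

    samples: list
    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("sample list must be non-empty")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")

    def validate(self) -> None:
        sample_set = set(self.samples)
        seen_order: dict = {}
        prev_key = None
        for rec in self.records:
            rec.validate()
            if set(rec.genotypes) != sample_set:
                raise ValueError(
                    f"record {rec.chromosome}:{rec.position} genotype slots "
                    f"{sorted(rec.genotypes)} != samples {sorted(sample_set)}")
            idx = seen_order.setdefault(rec.chromosome, len(seen_order))
            key = (idx, rec.position)
            if prev_key is not None and key < prev_key:
                raise ValueError(
                    f"records not sorted at {rec.chromosome}:{rec.position}")
            prev_key = key

    def sort(self, chrom_order: Optional[Sequence[str]] = None) -> None:
        """Sort records in place; chromosome order defaults to first appearance."""
        if chrom_order is None:
            chrom_order = list(dict.fromkeys(r.chromosome for r in self.records))
        rank = {c: i for i, c in enumerate(chrom_order)}
        self.records.sort(key=lambda r: (rank.get(r.chromosome, len(rank)), r.position))

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneInterval:
    """A gene span in BED convention (0-based half-open)."""

    chromosome: str
    start: int
    end: int
    gene_name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.start}>={self.end} "
                             f"for {self.gene_name}")


def _genotype_from_pysam(gt: tuple) -> Genotype:
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return None
    return tuple(int(a) for a in gt)


def read_merged_vcf(path: str | os.PathLike) -> MergedVariantTable:
    """Read a multi-sample VCF into a :class:`MergedVariantTable`.

    Annotations are taken from site-level INFO (the seven keys in
    :data:`ANNOTATION_KEYS`, when present); genotypes from FORMAT/GT with
    missing calls ("./." or ".") preserved as None.
    """
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if not samples:
            raise FormatError(f"{path}: VCF header names no samples")
        if "GT" not in vf.header.formats:
            raise FormatError(f"{path}: FORMAT/GT is not declared in the header")
        table = MergedVariantTable(samples=samples)
        for rec in vf:
            annotations = {}
            for key in ANNOTATION_KEYS:
                if key in rec.info:
                    value = rec.info[key]
                    if isinstance(value, tuple):
                        value = value[0]
                    annotations[key] = float(value)
            genotypes = {}
            for sample in samples:
                fmt = rec.samples[sample]
                if "GT" not in fmt:
                    raise FormatError(
                        f"{path}: record {rec.chrom}:{rec.pos} lacks GT")
                genotypes[sample] = _genotype_from_pysam(fmt["GT"])
            table.records.append(VariantRecord(
                chromosome=rec.chrom,
                position=rec.pos,
                ref_allele=rec.ref,
                alt_alleles=tuple(rec.alts or ()),
                annotations=annotations,
                genotypes=genotypes,
            ))
    table.validate()
    return table


def _build_header(table: MergedVariantTable,
                  contig_lengths: Optional[Mapping[str, int]] = None
                  ) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    contigs = list(dict.fromkeys(r.chromosome for r in table.records))
    for name in contigs:
        if contig_lengths and name in contig_lengths:
            header.contigs.add(name, length=int(contig_lengths[name]))
        else:
            header.contigs.add(name)
    header.info.add("DP", 1, "Integer", "Approximate read depth")
    for key in ANNOTATION_KEYS:
        if key == "DP":
            continue
        header.info.add(key, 1, "Float", f"{key} variant-calling annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in table.samples:
        header.add_sample(sample)
    return header


def write_vcf(table: MergedVariantTable, path: str | os.PathLike,
              contig_lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write the table as an uncompressed VCF 4.2 file.

    INFO keys are emitted in the fixed order of :data:`ANNOTATION_KEYS`;
    haploid genotypes are written as a single allele index. htslib stores
    Float INFO values as 32-bit floats, so annotations round-trip at
    float32 precision.
    """
    table.validate()
    header = _build_header(table, contig_lengths)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for rec in table.records:
            vrec = out.new_record(
                contig=rec.chromosome,
                start=rec.position - 1,
                alleles=(rec.ref_allele, *rec.alt_alleles),
            )
            for key in ANNOTATION_KEYS:
                if key in rec.annotations:
                    value = rec.annotations[key]
                    vrec.info[key] = int(round(value)) if key == "DP" else float(value)
            for sample in table.samples:
                gt = rec.genotypes[sample]
                vrec.samples[sample]["GT"] = gt if gt is not None else (None,)
                vrec.samples[sample].phased = False
            out.write(vrec)


def read_gene_bed(path: str | os.PathLike) -> list:
    """Read a BED4 gene annotation, returning intervals sorted per chromosome."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 tab-separated "
                                  f"columns, got {len(fields)}")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append(GeneInterval(chrom, start, end, name))
    intervals.sort(key=lambda g: (g.chromosome, g.start, g.end, g.gene_name))
    return intervals


def read_pedigree(path: str | os.PathLike):
    """Read a 4-column pedigree file (id, father, mother, sex; "0" = unknown)."""
    from .inbreeding import Individual, Pedigree

    individuals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated "
                                  f"columns, got {len(fields)}")
            iid, father, mother, sex = fields[:4]
            individuals.append(Individual(
                id=iid,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
                sex=None if sex == "0" else sex,
            ))
    return Pedigree(individuals)


def write_pedigree(pedigree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for ind in pedigree:
            fh.write("\t".join([ind.id, ind.father or "0", ind.mother or "0",
                                ind.sex or "0"]) + "\n")


def write_tsv(path: str | os.PathLike, header: Iterable[str],
              rows: Iterable[Sequence]) -> None:
    """Write a plain tab-separated report with a header line."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
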