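"""Seeded pedigree-structured genotype simulator with known truth.

The generator emulates the data the case-study pipeline consumes: a
quartet of dog genomes (a proband bred from a full-sib mating, its sire,
and two outbred controls) genotyped at a dense autosomal SNP backdrop,
plus an X chromosome and haploid mitochondrial genome, proband-private
de-novo SNVs (including a tight X cluster), variant-calling quality
annotations, and genotype missingness.

Founder haplotypes are drawn from a finite per-chromosome pool: a small
pool makes unrelated founders share haplotypes and so gives the breed a
tunable baseline autozygosity (the analogue of the controls' F_ROH of
roughly 0.13); ``founder_pool_size=None`` gives every founder unique
haplotypes ("clean" founders, baseline 0). Meioses place crossovers as a
Poisson process at ``cm_per_mb`` (Haldane model, no interference).
Ancestry labels ride along with the alleles, so the realized autozygous
fraction of any individual is known exactly.

Everything is driven by one ``numpy.random.default_rng`` seed and is
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .inbreeding import Individual, Pedigree
from .vcf_io import (CompartmentNaming, DEFAULT_NAMING, MergedVariantTable,
                     VariantRecord)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length_bp: int
    cm_per_mb: float
    compartment: str  # autosome | X | MT


@dataclass
class MarkerMap:
    """Simulated SNP positions with a genetic map and founder-pool frequencies."""

    chromosomes: tuple
    positions: dict  # chrom -> int64 array, strictly increasing 1-based
    refs: dict       # chrom -> array of ref bases
    alts: dict       # chrom -> array of alt bases
    freqs: dict      # chrom -> float array of alt-allele frequencies

    def spec(self, name: str) -> ChromSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def names(self, compartment: Optional[str] = None) -> list:
        return [c.name for c in self.chromosomes
                if compartment is None or c.compartment == compartment]

    @property
    def total_autosome_kb(self) -> float:
        return sum(c.length_bp for c in self.chromosomes
                   if c.compartment == "autosome") / 1000.0

    def n_markers(self, compartment: Optional[str] = None) -> int:
        return sum(self.positions[n].size for n in self.names(compartment))


@dataclass(frozen=True)
class DeNovoCluster:
    """A subset of the injected proband-only SNVs packed into a short span."""

    count: int = 8
    span_bp: int = 800
    compartment: str = "X"


@dataclass
class SimulationConfig:
    n_chromosomes: int = 4
    chrom_length_bp: int = 120_000_000
    n_markers_per_chrom: int = 40_000
    cm_per_mb: float = 1.0
    founder_pool_size: Optional[int] = 8  # None -> unique (clean) founders
    maf_low: float = 0.1
    maf_high: float = 0.5
    pedigree: Optional[Pedigree] = None  # None -> default sib-mating quartet
    samples: Optional[tuple] = None
    de_novo_count: int = 43
    de_novo_split: tuple = (20, 9, 14)  # autosome / X / MT
    de_novo_cluster: DeNovoCluster = field(default_factory=DeNovoCluster)
    annotation_fail_fraction: float = 0.05
    missing_rate: float = 0.002
    include_x: bool = True
    include_mt: bool = True
    mt_length_bp: int = 16_727
    mt_markers: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founder_pool_size is not None and self.founder_pool_size < 2:
            raise ValueError("founder_pool_size must be >= 2 (or None)")
        if not (0 < self.maf_low <= self.maf_high < 1):
            raise ValueError("need 0 < maf_low <= maf_high < 1")
        for rate in (self.annotation_fail_fraction, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if min(self.n_chromosomes, self.chrom_length_bp,
               self.n_markers_per_chrom, self.de_novo_count + 1) < 1:
            raise ValueError("counts must be positive")


def default_quartet_pedigree() -> Pedigree:
    """The case-study family: proband = offspring of two full sibs; the sire
    is sequenced alongside two outbred controls bred from separate founder
    pairs."""
    return Pedigree([
        Individual("GF", sex="M"), Individual("GM", sex="F"),
        Individual("CF1", sex="M"), Individual("CF2", sex="F"),
        Individual("CF3", sex="M"), Individual("CF4", sex="F"),
        Individual("sire", father="GF", mother="GM", sex="M"),
        Individual("dam", father="GF", mother="GM", sex="F"),
        Individual("proband", father="sire", mother="dam", sex="F"),
        Individual("ctrl1", father="CF1", mother="CF2", sex="M"),
        Individual("ctrl2", father="CF3", mother="CF4", sex="M"),
    ])


DEFAULT_SAMPLES = ("proband", "sire", "ctrl1", "ctrl2")


def _unique_sorted_positions(rng: np.random.Generator, length_bp: int,
                             n: int) -> np.ndarray:
    """n distinct sorted 1-based positions in [1, length_bp], memory-frugal."""
    chosen = np.unique(rng.integers(1, length_bp + 1, size=int(n * 1.1) + 8))
    while chosen.size < n:
        extra = rng.integers(1, length_bp + 1, size=n)
        chosen = np.unique(np.concatenate([chosen, extra]))
    if chosen.size > n:
        chosen = np.sort(rng.choice(chosen, size=n, replace=False))
    return chosen.astype(np.int64)


def simulate_map(config: SimulationConfig,
                 rng: Optional[np.random.Generator] = None) -> MarkerMap:
    """Draw marker positions, alleles and founder-pool allele frequencies."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = [ChromSpec(f"chr{i + 1}", config.chrom_length_bp, config.cm_per_mb,
                        "autosome")
              for i in range(config.n_chromosomes)]
    if config.include_x:
        chroms.append(ChromSpec("chrX", config.chrom_length_bp,
                                config.cm_per_mb, "X"))
    if config.include_mt:
        chroms.append(ChromSpec("chrM", config.mt_length_bp, 0.0, "MT"))
    positions, refs, alts, freqs = {}, {}, {}, {}
    for c in chroms:
        n = config.mt_markers if c.compartment == "MT" else config.n_markers_per_chrom
        n = min(n, c.length_bp)
        pos = _unique_sorted_positions(rng, c.length_bp, n)
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        positions[c.name] = pos.astype(np.int64)
        refs[c.name] = _BASES[ref_idx]
        alts[c.name] = _BASES[alt_idx]
        freqs[c.name] = rng.uniform(config.maf_low, config.maf_high, size=n)
    return MarkerMap(tuple(chroms), positions, refs, alts, freqs)


# A haplotype is a pair (alleles uint8, labels int64); a diploid genome holds
# two per chromosome, the MT genome one.
Haplotype = Tuple[np.ndarray, np.ndarray]


def simulate_founders(marker_map: MarkerMap, founder_ids: Sequence[str],
                      pool_size: Optional[int],
                      rng: np.random.Generator) -> Dict[str, dict]:
    """Assign each founder two haplotypes per diploid chromosome (one for MT).

    Per chromosome, a pool of haplotypes is drawn marker-by-marker from the
    map's allele frequencies; founders draw from the pool with replacement
    (``pool_size`` haplotypes) or, when ``pool_size`` is None, each founder
    receives its own freshly drawn haplotypes. The pool index is carried as
    the ancestry label, so identity of labels is identity by descent.
    """
    if pool_size is not None and pool_size < 2:
        raise ValueError("pool_size must be >= 2 (or None)")
    n_f = len(founder_ids)
    haps: Dict[str, dict] = {fid: {} for fid in founder_ids}
    for c in marker_map.chromosomes:
        freq = marker_map.freqs[c.name]
        copies = 1 if c.compartment == "MT" else 2
        effective_pool = pool_size if pool_size is not None else copies * n_f
        pool = (rng.random((effective_pool, freq.size)) < freq).astype(np.uint8)
        if pool_size is None:
            picks = np.arange(copies * n_f).reshape(n_f, copies)
        else:
            picks = rng.integers(0, effective_pool, size=(n_f, copies))
        for k, fid in enumerate(founder_ids):
            haps[fid][c.name] = tuple(
                (pool[picks[k, a]].copy(),
                 np.full(freq.size, picks[k, a], dtype=np.int64))
                for a in range(copies))
    return haps


def _gamete(parent_haps: Tuple[Haplotype, Haplotype], positions: np.ndarray,
            spec: ChromSpec, rng: np.random.Generator) -> Haplotype:
    """One meiosis: Poisson crossovers (Haldane), random start phase."""
    morgans = spec.length_bp * spec.cm_per_mb / 1e6 / 100.0
    n_cx = rng.poisson(morgans) if morgans > 0 else 0
    phase = int(rng.integers(0, 2))
    if n_cx == 0:
        which = np.full(positions.size, phase)
    else:
        cuts = np.sort(rng.uniform(0, spec.length_bp, size=n_cx))
        which = (phase + np.searchsorted(cuts, positions)) % 2
    (a0, l0), (a1, l1) = parent_haps
    return (np.where(which == 0, a0, a1).astype(np.uint8),
            np.where(which == 0, l0, l1))


def gene_drop(pedigree: Pedigree, founder_haps: Dict[str, dict],
              marker_map: MarkerMap,
              rng: np.random.Generator) -> Dict[str, dict]:
    """Transmit founder haplotypes through the pedigree.

    Diploid chromosomes recombine per :func:`_gamete`; the mitochondrial
    genome is copied from the mother unchanged (haploid, maternal).
    Returns haplotypes for every individual, founders included.
    """
    genomes: Dict[str, dict] = {}
    for iid in pedigree.topological_order():
        ind = pedigree[iid]
        if ind.father is None and ind.mother is None:
            if iid not in founder_haps:
                raise ValueError(f"founder {iid!r} has no haplotypes")
            genomes[iid] = founder_haps[iid]
            continue
        if ind.father is None or ind.mother is None:
            raise ValueError(f"{iid}: non-founders need both parents")
        genome: dict = {}
        for c in marker_map.chromosomes:
            pos = marker_map.positions[c.name]
            if c.compartment == "MT":
                mt = genomes[ind.mother][c.name][0]
                genome[c.name] = ((mt[0].copy(), mt[1].copy()),)
            else:
                genome[c.name] = (
                    _gamete(genomes[ind.father][c.name], pos, c, rng),
                    _gamete(genomes[ind.mother][c.name], pos, c, rng))
        genomes[iid] = genome
    return genomes


@dataclass
class SimResult:
    """A simulated dataset with full truth."""

    config: SimulationConfig
    marker_map: MarkerMap
    pedigree: Pedigree
    genomes: dict  # individual -> chrom -> tuple of haplotypes
    samples: tuple

    def genotype_codes(self, sample: str, compartment: str = "autosome") -> dict:
        """Per-chromosome (positions, codes) arrays for the ROH scanner."""
        out = {}
        for name in self.marker_map.names(compartment):
            haps = self.genomes[sample][name]
            pos = self.marker_map.positions[name]
            if len(haps) == 1:
                codes = np.where(haps[0][0] == 1, 2, 0)
            else:
                a, b = haps[0][0], haps[1][0]
                codes = np.where(a != b, 1, np.where(a == 1, 2, 0))
            out[name] = (pos, codes.astype(np.int64))
        return out

    def true_autozygosity(self, sample: str) -> float:
        """Fraction of autosomal markers whose two ancestry labels coincide."""
        same = total = 0
        for name in self.marker_map.names("autosome"):
            haps = self.genomes[sample][name]
            same += int(np.sum(haps[0][1] == haps[1][1]))
            total += haps[0][1].size
        return same / total

    def true_autozygous_segments(self, sample: str) -> list:
        """Maximal autosomal marker runs with identical ancestry labels."""
        segments = []
        for name in self.marker_map.names("autosome"):
            haps = self.genomes[sample][name]
            pos = self.marker_map.positions[name]
            same = haps[0][1] == haps[1][1]
            if not same.any():
                continue
            edges = np.flatnonzero(np.diff(
                np.concatenate(([0], same.view(np.int8), [0]))))
            for s, e in zip(edges[::2], edges[1::2]):
                segments.append((name, int(pos[s]), int(pos[e - 1])))
        return segments


def simulate_dataset(config: SimulationConfig = SimulationConfig()) -> SimResult:
    """Run map simulation, founder drawing and gene dropping under one seed."""
    rng = np.random.default_rng(config.seed)
    marker_map = simulate_map(config, rng)
    pedigree = config.pedigree or default_quartet_pedigree()
    samples = tuple(config.samples or
                    [s for s in DEFAULT_SAMPLES if s in pedigree])
    if not samples:
        raise ValueError("no samples to emit")
    founders = pedigree.founders()
    founder_haps = simulate_founders(marker_map, founders,
                                     config.founder_pool_size, rng)
    genomes = gene_drop(pedigree, founder_haps, marker_map, rng)
    return SimResult(config=config, marker_map=marker_map, pedigree=pedigree,
                     genomes=genomes, samples=samples)


def to_variant_table(sim: SimResult,
                     rng: Optional[np.random.Generator] = None,
                     missing_rate: Optional[float] = None,
                     drop_monomorphic: bool = True) -> MergedVariantTable:
    """Materialize the simulated genotypes as a merged multi-sample table.

    Sites where every sample is homozygous reference are dropped by
    default, as a joint variant caller would not report them. Genotype
    missingness is injected at ``missing_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(sim.config.seed + 1)
    if missing_rate is None:
        missing_rate = sim.config.missing_rate
    table = MergedVariantTable(samples=list(sim.samples))
    for c in sim.marker_map.chromosomes:
        pos = sim.marker_map.positions[c.name]
        refs = sim.marker_map.refs[c.name]
        alts = sim.marker_map.alts[c.name]
        allele_rows = []
        for s in sim.samples:
            haps = sim.genomes[s][c.name]
            allele_rows.append(np.stack([h[0] for h in haps]))  # (ploidy, m)
        any_alt = np.zeros(pos.size, dtype=bool)
        for row in allele_rows:
            any_alt |= (row == 1).any(axis=0)
        keep = any_alt if drop_monomorphic else np.ones(pos.size, dtype=bool)
        idx = np.flatnonzero(keep)
        miss = rng.random((len(sim.samples), idx.size)) < missing_rate
        for col, m in enumerate(idx):
            genotypes = {}
            for si, s in enumerate(sim.samples):
                if miss[si, col]:
                    genotypes[s] = None
                else:
                    genotypes[s] = tuple(int(a) for a in allele_rows[si][:, m])
            table.records.append(VariantRecord(
                chromosome=c.name, position=int(pos[m]),
                ref_allele=str(refs[m]), alt_alleles=(str(alts[m]),),
                genotypes=genotypes))
    return table


def _random_allele_pair(rng: np.random.Generator) -> tuple:
    ref = int(rng.integers(0, 4))
    alt = (ref + int(rng.integers(1, 4))) % 4
    return str(_BASES[ref]), str(_BASES[alt])


def inject_unique_variants(table: MergedVariantTable, proband_id: str,
                           rng: np.random.Generator,
                           count: int = 43,
                           split: tuple = (20, 9, 14),
                           cluster: Optional[DeNovoCluster] = DeNovoCluster(),
                           naming: CompartmentNaming = DEFAULT_NAMING
                           ) -> Tuple[MergedVariantTable, list]:
    """Add proband-private SNVs at positions off the existing markers.

    ``split`` apportions ``count`` variants over (autosome, X, MT); the
    cluster spec packs part of one compartment's quota into a contiguous
    span (the analogue of the case's eight X-linked SNVs within 800 bp).
    The proband is heterozygous (haploid-alt on MT) and every control
    homozygous (haploid) reference. Returns the new sorted table and the
    list of injected (chrom, pos, ref, alt) keys.
    """
    if sum(split) != count:
        raise ValueError(f"split {split} does not sum to count {count}")
    if proband_id not in table.samples:
        raise ValueError(f"unknown proband {proband_id!r}")
    chrom_order = list(dict.fromkeys(r.chromosome for r in table.records))
    by_comp: dict = {"autosome": [], "X": [], "MT": []}
    occupied: dict = {}
    max_pos: dict = {}
    for rec in table.records:
        by_comp.setdefault(naming.compartment_of(rec.chromosome), [])
        occupied.setdefault(rec.chromosome, set()).add(rec.position)
        max_pos[rec.chromosome] = max(max_pos.get(rec.chromosome, 1), rec.position)
    for comp in ("autosome", "X", "MT"):
        by_comp[comp] = [c for c in chrom_order
                         if naming.compartment_of(c) == comp]

    def draw_position(chrom: str, lo: int = 1, hi: Optional[int] = None) -> int:
        hi = hi if hi is not None else max_pos[chrom]
        taken = occupied[chrom]
        for _ in range(10_000):
            p = int(rng.integers(lo, hi + 1))
            if p not in taken:
                taken.add(p)
                return p
        raise ValueError(f"no free position in {chrom}:{lo}-{hi}")

    planned = []  # (chrom, pos, haploid)
    for comp, quota in zip(("autosome", "X", "MT"), split):
        if quota == 0:
            continue
        chroms = by_comp[comp]
        if not chroms:
            raise ValueError(f"no {comp} chromosome available for injection")
        haploid = comp == "MT"
        remaining = quota
        if cluster is not None and cluster.compartment == comp:
            if cluster.count > quota:
                raise ValueError("cluster larger than compartment quota")
            if cluster.span_bp < cluster.count:
                raise ValueError(f"span {cluster.span_bp} bp too small for "
                                 f"{cluster.count} distinct positions")
            chrom = chroms[0]
            anchor = int(rng.integers(1, max(2, max_pos[chrom] - cluster.span_bp)))
            for _ in range(cluster.count):
                planned.append((chrom, draw_position(
                    chrom, anchor, anchor + cluster.span_bp - 1), haploid))
            remaining -= cluster.count
        for _ in range(remaining):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            planned.append((chrom, draw_position(chrom), haploid))

    controls = [s for s in table.samples if s != proband_id]
    injected = []
    new_records = []
    for chrom, pos, haploid in planned:
        ref, alt = _random_allele_pair(rng)
        genotypes = {proband_id: (1,) if haploid else (0, 1)}
        for s in controls:
            genotypes[s] = (0,) if haploid else (0, 0)
        new_records.append(VariantRecord(
            chromosome=chrom, position=pos, ref_allele=ref,
            alt_alleles=(alt,), genotypes=genotypes))
        injected.append((chrom, pos, ref, alt))
    out = MergedVariantTable(samples=list(table.samples),
                             records=list(table.records) + new_records)
    out.sort(chrom_order)
    return out, injected


#: (annotation, passing draw range, failing draw range) per named hard filter.
_ANNOTATION_RANGES = {
    "QD": ((5.0, 35.0), (0.05, 1.9)),
    "FS": ((0.0, 45.0), (61.0, 150.0)),
    "MQ": ((57.0, 60.0), (30.0, 55.5)),
    "SOR": ((0.4, 2.6), (3.1, 8.0)),
    "MQRankSum": ((-6.0, 6.0), (-20.0, -12.6)),
    "ReadPosRankSum": ((-5.0, 5.0), (-15.0, -8.1)),
}


def attach_quality_annotations(table: MergedVariantTable, fail_fraction: float,
                               rng: np.random.Generator
                               ) -> Tuple[MergedVariantTable, list]:
    """Draw calling annotations for every record, with labelled failures.

    Each record gets DP plus the six filterable annotations drawn inside
    the passing region; a ``fail_fraction`` of records instead violate
    exactly one named threshold. Returns the table (annotated in place)
    and the parallel truth labels (failed filter name or None).
    """
    if not 0.0 <= fail_fraction <= 1.0:
        raise ValueError("fail_fraction must be in [0, 1]")
    names = list(_ANNOTATION_RANGES)
    labels = []
    for rec in table.records:
        ann = {"DP": float(rng.integers(20, 61))}
        for name, (lo_hi, _) in _ANNOTATION_RANGES.items():
            ann[name] = round(float(rng.uniform(*lo_hi)), 3)
        label = None
        if rng.random() < fail_fraction:
            label = names[int(rng.integers(0, len(names)))]
            ann[label] = round(float(rng.uniform(*_ANNOTATION_RANGES[label][1])), 3)
        rec.annotations = ann
        labels.append(label)
    return table, labels
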