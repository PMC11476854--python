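import numpy as np
import pytest

from autozyg.vcf_io import MergedVariantTable, VariantRecord


def make_record(chrom="chr1", pos=100, ref="A", alts=("G",), genotypes=None,
                annotations=None, samples=("proband", "ctrl")):
    if genotypes is None:
        genotypes = {s: (0, 0) for s in samples}
    return VariantRecord(chromosome=chrom, position=pos, ref_allele=ref,
                         alt_alleles=tuple(alts),
                         annotations=dict(annotations or {}),
                         genotypes=dict(genotypes))


def make_table(records, samples=("proband", "ctrl")):
    return MergedVariantTable(samples=list(samples), records=list(records))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_table(rng, n_records=200, samples=("proband", "c1", "c2"),
                 missing_rate=0.05, chroms=("chr1", "chr2")):
    """Random single-alt SNV table with non-trivial genotype diversity."""
    records = []
    per_chrom = {}
    for _ in range(n_records):
        chrom = chroms[int(rng.integers(len(chroms)))]
        per_chrom.setdefault(chrom, set())
        while True:
            pos = int(rng.integers(1, 10_000_000))
            if pos not in per_chrom[chrom]:
                per_chrom[chrom].add(pos)
                break
        genotypes = {}
        for s in samples:
            if rng.random() < missing_rate:
                genotypes[s] = None
            else:
                genotypes[s] = (int(rng.integers(2)), int(rng.integers(2)))
        records.append(make_record(chrom=chrom, pos=pos, ref="A", alts=("G",),
                                   genotypes=genotypes, samples=samples))
    table = make_table(records, samples=samples)
    table.sort()
    return table
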