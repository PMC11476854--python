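"""Simulator truth: Hardy-Weinberg, Mendelian transmission, injection closure."""

import numpy as np
import pytest
from scipy import stats

from autozyg import synthetic_data as sd
from autozyg import variant_filters as vf
from autozyg.synthetic_data import (DeNovoCluster, SimulationConfig,
                                    default_quartet_pedigree, gene_drop,
                                    simulate_dataset, simulate_founders,
                                    simulate_map, to_variant_table)

SMALL = dict(n_chromosomes=2, chrom_length_bp=10_000_000,
             n_markers_per_chrom=1500, missing_rate=0.0)


def small_config(**kw):
    return SimulationConfig(**{**SMALL, **kw})


class TestSimulateMap:
    def test_counts_and_sortedness(self):
        m = simulate_map(small_config(seed=1))
        assert m.n_markers("autosome") == 3000
        for name in m.names():
            pos = m.positions[name]
            assert np.all(np.diff(pos) > 0) and pos[0] >= 1

    def test_same_seed_identical(self):
        a = simulate_map(small_config(seed=5))
        b = simulate_map(small_config(seed=5))
        for name in a.names():
            assert np.array_equal(a.positions[name], b.positions[name])
            assert np.array_equal(a.freqs[name], b.freqs[name])

    def test_degenerate_maf_bounds(self):
        m = simulate_map(small_config(seed=2, maf_low=0.4, maf_high=0.4))
        assert np.allclose(m.freqs["chr1"], 0.4)

    def test_ref_alt_distinct(self):
        m = simulate_map(small_config(seed=3))
        assert not np.any(m.refs["chr1"] == m.alts["chr1"])


class TestSimulateFounders:
    def test_unique_pool_homozygosity_matches_hardy_weinberg(self):
        # with per-founder unique haplotypes, expected homozygosity per
        # marker is p^2 + (1-p)^2
        cfg = SimulationConfig(n_chromosomes=1, chrom_length_bp=50_000_000,
                               n_markers_per_chrom=10_000, include_x=False,
                               include_mt=False, seed=9)
        m = simulate_map(cfg)
        rng = np.random.default_rng(9)
        haps = simulate_founders(m, ["f1", "f2", "f3", "f4"], None, rng)
        p = m.freqs["chr1"]
        expected = p ** 2 + (1 - p) ** 2
        se = np.sqrt(np.sum(expected * (1 - expected))) / p.size
        for fid in haps:
            (a0, _), (a1, _) = haps[fid]["chr1"]
            observed = np.mean(a0 == a1)
            assert abs(observed - np.mean(expected)) < 3 * se + 3 / np.sqrt(p.size)

    def test_pool_of_two_gives_three_diplotypes(self):
        m = simulate_map(small_config(seed=4))
        rng = np.random.default_rng(4)
        haps = simulate_founders(m, [f"f{i}" for i in range(10)], 2, rng)
        for fid in haps:
            for chrom, copies in haps[fid].items():
                for _alleles, labels in copies:
                    assert set(np.unique(labels)) <= {0, 1}

    def test_same_seed_identical(self):
        m = simulate_map(small_config(seed=6))
        a = simulate_founders(m, ["x", "y"], 4, np.random.default_rng(6))
        b = simulate_founders(m, ["x", "y"], 4, np.random.default_rng(6))
        assert np.array_equal(a["x"]["chr1"][0][0], b["x"]["chr1"][0][0])


class TestGeneDrop:
    def test_mendelian_consistency_everywhere(self):
        sim = simulate_dataset(small_config(seed=12, founder_pool_size=6))
        ped = sim.pedigree
        for iid in ped.ids:
            ind = ped[iid]
            if ind.father is None:
                continue
            for c in sim.marker_map.chromosomes:
                child = sim.genomes[iid][c.name]
                if c.compartment == "MT":
                    mother = sim.genomes[ind.mother][c.name][0]
                    assert np.array_equal(child[0][0], mother[0])
                    continue
                for copy, parent in zip(child, (ind.father, ind.mother)):
                    (p0, _), (p1, _) = sim.genomes[parent][c.name]
                    assert np.all((copy[0] == p0) | (copy[0] == p1))

    def test_zero_recombination_transmits_intact_haplotypes(self):
        cfg = small_config(seed=13, cm_per_mb=0.0, founder_pool_size=None)
        sim = simulate_dataset(cfg)
        sire = sim.genomes["sire"]
        for name in sim.marker_map.names("autosome"):
            (c0, l0), _ = sim.genomes["proband"][name]
            # the proband's paternal haplotype is one of the sire's, intact
            assert any(np.array_equal(l0, parental[1])
                       for parental in sire[name])

    def test_sib_mating_autozygosity_plausible(self):
        cfg = SimulationConfig(n_chromosomes=8, chrom_length_bp=100_000_000,
                               n_markers_per_chrom=2000, include_x=False,
                               include_mt=False, founder_pool_size=None,
                               seed=14)
        f = simulate_dataset(cfg).true_autozygosity("proband")
        assert 0.02 < f < 0.6  # wide net; the mean is pinned elsewhere

    def test_cyclic_pedigree_rejected(self):
        from autozyg.inbreeding import Individual, Pedigree
        with pytest.raises(ValueError, match="cycle"):
            Pedigree([Individual("a", father="b", mother="c"),
                      Individual("b", father="a", mother="c"),
                      Individual("c")])

    def test_baseline_autozygosity_monotone_in_pool_size(self):
        means = []
        for pool in (2, 4, 16, 256):
            vals = []
            for seed in range(4):
                cfg = SimulationConfig(
                    n_chromosomes=8, chrom_length_bp=5_000_000,
                    n_markers_per_chrom=300, include_x=False,
                    include_mt=False, founder_pool_size=pool, seed=seed)
                sim = simulate_dataset(cfg)
                vals.extend(sim.true_autozygosity(s) for s in sim.samples)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2] >= means[3]


class TestToVariantTable:
    def test_monomorphic_sites_dropped_and_genotypes_match_haplotypes(self):
        sim = simulate_dataset(small_config(seed=15, founder_pool_size=4))
        table = to_variant_table(sim, rng=np.random.default_rng(0),
                                 missing_rate=0.0)
        assert 0 < len(table) <= sim.marker_map.n_markers()
        table.validate()
        by_chrom_pos = {}
        for c in sim.marker_map.chromosomes:
            pos = sim.marker_map.positions[c.name]
            for s in sim.samples:
                haps = sim.genomes[s][c.name]
                alleles = np.stack([h[0] for h in haps])
                by_chrom_pos[(c.name, s)] = (pos, alleles)
        for rec in table.records[::37]:
            for s in sim.samples:
                pos, alleles = by_chrom_pos[(rec.chromosome, s)]
                m = int(np.searchsorted(pos, rec.position))
                assert tuple(alleles[:, m]) == rec.genotypes[s]

    def test_missingness_rate_applied(self):
        sim = simulate_dataset(small_config(seed=16))
        table = to_variant_table(sim, rng=np.random.default_rng(1),
                                 missing_rate=0.2)
        n_slots = len(table) * len(sim.samples)
        n_missing = sum(1 for r in table.records
                        for g in r.genotypes.values() if g is None)
        assert n_missing / n_slots == pytest.approx(0.2, abs=0.02)


class TestInjectUniqueVariants:
    def _table(self, seed=17):
        sim = simulate_dataset(small_config(seed=seed, founder_pool_size=4))
        return sim, to_variant_table(sim, rng=np.random.default_rng(seed),
                                     missing_rate=0.0)

    def test_partition_mirrors_requested_split(self):
        _sim, table = self._table()
        rng = np.random.default_rng(2)
        out, injected = sd.inject_unique_variants(table, "proband", rng)
        assert len(injected) == 43
        new_keys = set(injected)
        new_records = [r for r in out.records
                       if (r.chromosome, r.position, r.ref_allele,
                           r.alt_alleles[0]) in new_keys]
        sub = sd.MergedVariantTable(samples=list(out.samples),
                                    records=new_records)
        assert vf.partition_by_compartment(sub) == {
            "autosome": 20, "X": 9, "MT": 14}

    def test_cluster_span_respected(self):
        _sim, table = self._table()
        rng = np.random.default_rng(3)
        out, injected = sd.inject_unique_variants(
            table, "proband", rng,
            cluster=DeNovoCluster(count=8, span_bp=800, compartment="X"))
        x_pos = sorted(p for c, p, _r, _a in injected if c == "chrX")
        # 8 of the 9 X variants lie within one 800 bp window
        diffs = [x_pos[i + 7] - x_pos[i] for i in range(len(x_pos) - 7)]
        assert min(diffs) < 800

    def test_count_zero_identity(self):
        _sim, table = self._table()
        out, injected = sd.inject_unique_variants(
            table, "proband", np.random.default_rng(4), count=0,
            split=(0, 0, 0), cluster=None)
        assert injected == [] and out.records == table.records

    def test_span_too_small_rejected(self):
        _sim, table = self._table()
        with pytest.raises(ValueError, match="too small"):
            sd.inject_unique_variants(
                table, "proband", np.random.default_rng(5),
                cluster=DeNovoCluster(count=9, span_bp=4, compartment="X"))

    def test_proband_unique_recovers_injection_exactly(self):
        # founder pool of 2 makes both pool haplotypes segregate among the
        # controls, so no natural proband-only alleles exist (asserted), and
        # the injected set is recovered exactly
        cfg = small_config(seed=18, founder_pool_size=2, maf_low=0.35,
                           maf_high=0.5)
        sim = simulate_dataset(cfg)
        table = to_variant_table(sim, rng=np.random.default_rng(18),
                                 missing_rate=0.0)
        natural = vf.proband_unique(table, "proband")
        assert natural.records == []
        out, injected = sd.inject_unique_variants(
            table, "proband", np.random.default_rng(19))
        unique = vf.proband_unique(out, "proband")
        got = {(r.chromosome, r.position, r.ref_allele, r.alt_alleles[0])
               for r in unique.records}
        assert got == set(injected)


class TestAttachQualityAnnotations:
    def _annotated(self, fail_fraction, n=1000, seed=20):
        rng = np.random.default_rng(seed)
        sim = simulate_dataset(small_config(seed=seed))
        table = to_variant_table(sim, rng=rng, missing_rate=0.0)
        table.records = table.records[:n]
        return sd.attach_quality_annotations(table, fail_fraction, rng)

    def test_zero_fail_fraction_all_pass(self):
        table, labels = self._annotated(0.0)
        verdicts = vf.apply_hard_filters(table, dp_rule=False)
        assert all(v.passed for v in verdicts)
        assert labels == [None] * len(table)

    def test_verdicts_match_truth_labels(self):
        table, labels = self._annotated(0.3)
        verdicts = vf.apply_hard_filters(table, dp_rule=False)
        for v, label in zip(verdicts, labels):
            assert v.reasons == ([] if label is None else [label])

    def test_fail_counts_roughly_uniform_across_filters(self):
        rng = np.random.default_rng(21)
        sim = simulate_dataset(small_config(seed=21, n_markers_per_chrom=4000))
        table = to_variant_table(sim, rng=rng, missing_rate=0.0)
        table.records = table.records[:6000]
        _t, labels = sd.attach_quality_annotations(table, 1.0, rng)
        counts = [labels.count(k) for k in sd._ANNOTATION_RANGES]
        assert stats.chisquare(counts).pvalue > 1e-3


def test_full_determinism_under_fixed_seed():
    a = simulate_dataset(small_config(seed=22))
    b = simulate_dataset(small_config(seed=22))
    for s in a.samples:
        for name in a.marker_map.names():
            for ha, hb in zip(a.genomes[s][name], b.genomes[s][name]):
                assert np.array_equal(ha[0], hb[0])
                assert np.array_equal(ha[1], hb[1])
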