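"""Synthetic genome/genotype/phenotype generator behaviour."""

import numpy as np
import pytest

from regionpred import annotate
from regionpred.simulate import (
    SystematicEffects,
    TraitArchitecture,
    inject_missingness,
    simulate_genome,
    simulate_genotypes,
    simulate_phenotypes,
)


class TestGenome:
    def test_default_genome_populates_all_five_region_classes(self, small_genome, small_partition):
        assert small_genome.n_snps == 1000
        for name, ids in small_partition.regions.items():
            assert ids, f"region {name} empty"

    def test_no_genes_puts_every_snp_in_igr(self):
        g = simulate_genome(1, 200_000, 0, 1e-3, seed=3)
        part = annotate.build_partition(g.snp_map, g)
        assert len(part["IGR"]) == g.n_snps
        assert not part["Genes1kb"]

    def test_seeded_determinism(self):
        a = simulate_genome(2, 300_000, 3, 1e-3, seed=7)
        b = simulate_genome(2, 300_000, 3, 1e-3, seed=7)
        assert a.snp_map == b.snp_map
        assert a.genes == b.genes

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(1, 0, 2, 1e-3, seed=1)
        with pytest.raises(ValueError):
            simulate_genome(1, 100_000, 2, -1.0, seed=1)

    def test_gene_models_are_nested_and_separated(self, small_genome):
        for g in small_genome.genes:
            for s, e in g.cds:
                assert any(es <= s and e <= ee for es, ee in g.exons)
            assert g.exons[0][0] >= g.start and g.exons[-1][1] <= g.end
        starts = sorted((g.start, g.end) for g in small_genome.genes)
        for (s1, e1), (s2, e2) in zip(starts, starts[1:]):
            assert s2 - e1 > 2000, "1kb flanks of neighbouring genes must not overlap"


class TestGenotypes:
    def test_hwe_proportions_at_half(self):
        snp_map = [(f"s{j}", "chr1", j + 1) for j in range(50)]
        geno = simulate_genotypes(4000, snp_map, maf_range=(0.5, 0.5), seed=4)
        for j in range(50):
            counts = np.bincount(geno.dosages[:, j].astype(int), minlength=3) / 4000
            assert np.allclose(counts, [0.25, 0.5, 0.25], atol=0.05)

    def test_observed_frequency_tracks_drawn_frequency(self):
        snp_map = [(f"s{j}", "chr1", j + 1) for j in range(500)]
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.5, size=500)  # regenerate the drawn p_j
        geno = simulate_genotypes(1000, snp_map, maf_range=(0.05, 0.5), seed=5)
        obs = geno.allele_frequencies()
        se = np.sqrt(p * (1 - p) / (2 * 1000))
        assert (np.abs(obs - p) <= 3.5 * se).mean() > 0.99

    def test_seeded_determinism_and_small_n_rejected(self):
        snp_map = [("s1", "chr1", 1), ("s2", "chr1", 2)]
        a = simulate_genotypes(10, snp_map, seed=6)
        b = simulate_genotypes(10, snp_map, seed=6)
        assert np.array_equal(a.dosages, b.dosages)
        with pytest.raises(ValueError):
            simulate_genotypes(1, snp_map, seed=6)

    def test_ld_mode_induces_local_ld(self):
        snp_map = [(f"s{j}", "chr1", j + 1) for j in range(100)]
        le = simulate_genotypes(400, snp_map, maf_range=(0.3, 0.5), seed=8)
        ld = simulate_genotypes(400, snp_map, maf_range=(0.3, 0.5), seed=8,
                                ld_mode=True)

        def adjacent_r2(g):
            x = g.dosages
            keep = x.std(axis=0) > 0
            x = x[:, keep]
            r = [np.corrcoef(x[:, j], x[:, j + 1])[0, 1] ** 2
                 for j in range(x.shape[1] - 1)]
            return float(np.mean(r))

        assert adjacent_r2(ld) > 5 * adjacent_r2(le)


class TestPhenotypes:
    def test_zero_heritability_gives_zero_genetic_values(self, small_genotypes, small_partition):
        arch = TraitArchitecture("ALL", h2=0.0)
        _, truth = simulate_phenotypes(small_genotypes, small_partition, arch, seed=9)
        assert np.all(truth.genetic_values == 0)
        assert truth.realized_h2 == 0.0

    def test_full_heritability_means_phenotype_equals_genetic_value(self, small_genotypes, small_partition):
        arch = TraitArchitecture("ALL", h2=1.0)
        pheno, truth = simulate_phenotypes(small_genotypes, small_partition, arch,
                                           seed=10, mu=5.0)
        assert np.allclose(pheno["y"].to_numpy() - 5.0, truth.genetic_values)

    def test_realized_heritability_near_target_across_seeds(self):
        snp_map = [(f"s{j}", "chr1", j + 1) for j in range(200)]
        geno = simulate_genotypes(2000, snp_map, seed=20)
        arch = TraitArchitecture("ALL", h2=0.30)
        ratios = [simulate_phenotypes(geno, None, arch, seed=s)[1].realized_h2
                  for s in range(20)]
        assert all(0.25 <= r <= 0.35 for r in ratios)

    def test_causal_effects_confined_to_target_class(self, small_genotypes, small_partition):
        arch = TraitArchitecture("CDS", h2=0.5)
        _, truth = simulate_phenotypes(small_genotypes, small_partition, arch, seed=11)
        nonzero = set(truth.snp_effects[truth.snp_effects != 0].index)
        assert nonzero and nonzero <= set(small_partition["CDS"])

    def test_realized_h2_tightens_with_sample_size(self, small_genome, small_partition):
        arch = TraitArchitecture("ALL", h2=0.30)
        devs = []
        for n in (200, 1000, 5000):
            geno = simulate_genotypes(n, small_genome.snp_map[:200], seed=12)
            errs = [abs(simulate_phenotypes(geno, None, arch, seed=s)[1].realized_h2 - 0.30)
                    for s in range(5)]
            devs.append(np.mean(errs))
        assert devs[2] < devs[0]

    def test_systematic_level_size_profile(self, small_genotypes, small_partition):
        arch = TraitArchitecture("ALL", h2=0.30,
                                 systematic=SystematicEffects(variance_share=0.2))
        pheno, _ = simulate_phenotypes(small_genotypes, small_partition, arch, seed=13)
        counts = pheno["level"].value_counts()
        n = len(pheno)
        singletons = (counts == 1).sum() / n
        doubletons = 2 * (counts == 2).sum() / n
        assert abs(singletons - 0.40) < 0.05
        assert abs(doubletons - 0.28) < 0.06

    def test_h2_one_with_systematic_effect_rejected(self):
        with pytest.raises(ValueError):
            TraitArchitecture("ALL", h2=1.0, systematic=SystematicEffects())


class TestMissingness:
    def test_zero_rates_identity(self, small_genotypes):
        out = inject_missingness(small_genotypes, 0.0, 0.0, seed=1)
        assert np.array_equal(out.dosages, small_genotypes.dosages)

    def test_per_snp_rate_hits_target_call_rate(self, small_genome):
        geno = simulate_genotypes(1000, small_genome.snp_map[:20], seed=14)
        rates = np.zeros(20)
        rates[0] = 0.10
        out = inject_missingness(geno, snp_rates=rates, seed=15)
        assert abs(out.call_rates()[0] - 0.90) < 0.03
        assert np.isnan(out.dosages[:, 1:]).sum() == 0

    def test_seeded_repeatability_and_bad_rate(self, small_genotypes):
        a = inject_missingness(small_genotypes, 0.05, 0.02, seed=16)
        b = inject_missingness(small_genotypes, 0.05, 0.02, seed=16)
        assert np.array_equal(a.dosages, b.dosages, equal_nan=True)
        with pytest.raises(ValueError):
            inject_missingness(small_genotypes, 1.0, 0.0, seed=16)
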