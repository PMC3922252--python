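#!/usr/bin/env python
"""Simulate the synthetic study population.

Generates a two-chromosome annotated genome (~2,000 SNPs, 12 genes), 250
genotyped animals, and three traits that mirror the study's architectures:

* bw  — body-weight-like, genome-wide additive effects, h2 = 0.30
* bm  — breast-meat-like, effects concentrated in genic SNPs, h2 = 0.33
* hhp — egg-production-like, genome-wide additive effects, h2 = 0.19

Each trait carries a many-level random systematic factor (~40% of animals in
singleton levels, ~28% in doubletons). Genotypes are written both complete
(for the truth record) and with ~1% random missingness, which the QC step
will filter and impute.

Outputs under results/data/.
"""

import os

import numpy as np

from regionpred import annotate, simulate

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "data")
SEED = 2024
N_ANIMALS = 250

TRAITS = {
    "bw": simulate.TraitArchitecture("ALL", h2=0.30,
                                     systematic=simulate.SystematicEffects(0.20)),
    "bm": simulate.TraitArchitecture("Genes", h2=0.33,
                                     systematic=simulate.SystematicEffects(0.20)),
    "hhp": simulate.TraitArchitecture("ALL", h2=0.19,
                                      systematic=simulate.SystematicEffects(0.15)),
}


def main():
    os.makedirs(OUT, exist_ok=True)
    genome = simulate.simulate_genome(2, 500_000, 6, 2e-3, seed=SEED)
    genome.to_gff3(os.path.join(OUT, "genome.gff3"))
    part = annotate.build_partition(genome.snp_map, genome)
    print(f"genome: {genome.n_snps} SNPs, {len(genome.genes)} genes")
    print("region sizes:", part.sizes())

    complete = simulate.simulate_genotypes(N_ANIMALS, genome.snp_map, seed=SEED + 1)
    with_gaps = simulate.inject_missingness(complete, snp_rates=0.01,
                                            animal_rates=0.005, seed=SEED + 2)
    with_gaps.to_vcf(os.path.join(OUT, "genotypes.vcf"))
    with_gaps.to_dosage_tsv(os.path.join(OUT, "dosages_raw.tsv"))
    print(f"genotypes: {complete.n_animals} animals, "
          f"{np.isnan(with_gaps.dosages).mean():.3%} entries missing")

    for i, (name, arch) in enumerate(TRAITS.items()):
        pheno, truth = simulate.simulate_phenotypes(complete, part, arch,
                                                    seed=SEED + 10 + i)
        pheno.to_csv(os.path.join(OUT, f"pheno_{name}.tsv"), sep="\t", index=False)
        truth.to_tsv(os.path.join(OUT, f"truth_{name}.tsv"))
        print(f"trait {name}: target h2 = {arch.h2}, realized = "
              f"{truth.realized_h2:.3f}, {pheno['level'].nunique()} systematic levels")

    with open(os.path.join(OUT, "config.txt"), "w") as fh:
        fh.write(f"seed\t{SEED}\nn_animals\t{N_ANIMALS}\n"
                 "n_chrom\t2\nchrom_length\t500000\ngenes_per_chrom\t6\n"
                 "snp_density\t0.002\nsnp_missing_rate\t0.01\n"
                 "animal_missing_rate\t0.005\n")
        for name, arch in TRAITS.items():
            fh.write(f"trait_{name}\ttarget={arch.target_class} h2={arch.h2}\n")


if __name__ == "__main__":
    main()
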