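"""Reference experiments: parameter recovery and region-comparison patterns.

These procedures regenerate data under the study's stated conditions and
measure what the pipeline recovers; the test suite and the reproduction
script both run them. All randomness derives from a single master seed via
``numpy.random.SeedSequence`` spawn keys.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import annotate, cv, kernel, krr, simulate

__all__ = ["heritability_recovery", "region_pattern_cv"]


def _seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=key).generate_state(1)[0]
               % (2 ** 31))


def heritability_recovery(
    h2: float,
    n_animals: int = 1000,
    n_snps: int = 5000,
    n_seeds: int = 10,
    master_seed: int = 1,
    mcmc: krr.MCMCConfig | None = None,
) -> dict:
    """Posterior-mean genomic variance ratio under a genome-wide architecture.

    Per replicate: simulate unrelated HWE genotypes, put additive effects on
    every SNP with residual variance scaled to the target heritability, build
    the all-SNP VanRaden kernel, fit the kernel Bayesian ridge regression to
    the centered phenotype, and record the posterior mean of
    var(K alpha) / (var(K alpha) + sigma2_e). Returns the mean over
    replicates plus the per-replicate values.
    """
    snp_map = [(f"s{j}", "chr1", j + 1) for j in range(n_snps)]
    values = []
    for rep in range(n_seeds):
        geno = simulate.simulate_genotypes(
            n_animals, snp_map, seed=_seed(master_seed, rep, 0))
        pheno, _ = simulate.simulate_phenotypes(
            geno, None, simulate.TraitArchitecture("ALL", h2=h2),
            seed=_seed(master_seed, rep, 1))
        y = pheno["y"].to_numpy()
        y = y - y.mean()
        km = kernel.vanraden_g(geno)
        cfg = mcmc or krr.MCMCConfig.reduced(seed=0)
        cfg = krr.MCMCConfig(cfg.burn_in, cfg.draws, cfg.thin,
                             seed=_seed(master_seed, rep, 2))
        chain = krr.gibbs_krr(y, km, config=cfg)
        values.append(krr.genomic_variance_ratio(chain)["mean"])
    return {"h2": h2, "mean": float(np.mean(values)), "values": values,
            "n_animals": n_animals, "n_snps": n_snps}


def region_pattern_cv(
    target_class: str,
    h2: float,
    master_seed: int = 1,
    n_animals: int = 200,
    regions: tuple[str, ...] = ("CDS", "IGR", "ALL"),
    matched_igr_for: tuple[str, ...] = ("CDS",),
    replicates: int = 15,
    folds: int = 10,
    mcmc: krr.MCMCConfig | None = None,
) -> pd.DataFrame:
    """Replicated k-fold CV of region kernels on one simulated architecture.

    Simulates a two-chromosome annotated genome (~2,000 SNPs), phenotypes
    with additive effects confined to ``target_class`` (or genome-wide for
    "ALL"), then scores each region kernel plus per-replicate size-matched
    intergenic controls. Returns the long-format fold correlations.
    """
    genome = simulate.simulate_genome(2, 500_000, 6, 2e-3,
                                      seed=_seed(master_seed, 100))
    geno = simulate.simulate_genotypes(n_animals, genome.snp_map,
                                       seed=_seed(master_seed, 101))
    partition = annotate.build_partition(genome.snp_map, genome)
    partition.validate(geno.snp_ids)
    pheno, _ = simulate.simulate_phenotypes(
        geno, partition, simulate.TraitArchitecture(target_class, h2=h2),
        seed=_seed(master_seed, 102))
    y = pheno["y"].to_numpy()
    y = y - y.mean()
    plan = cv.make_folds(geno.animal_ids, folds, replicates,
                         seed=_seed(master_seed, 103))
    base = mcmc or krr.MCMCConfig.reduced(seed=0)

    frames = []
    for ridx, name in enumerate(regions):
        subset = None if name == "ALL" else partition[name]
        km = kernel.vanraden_g(geno, subset)
        cfg = krr.MCMCConfig(base.burn_in, base.draws, base.thin,
                             seed=_seed(master_seed, 104, ridx))
        frames.append(cv.run_cv(km, y, plan, mcmc=cfg, region_name=name).records)
    for gidx, name in enumerate(matched_igr_for):
        recs = []
        for rep in range(replicates):
            sample = annotate.sample_matched_igr(
                partition, name, seed=_seed(master_seed, 105, gidx, rep))
            km = kernel.vanraden_g(geno, sample.snp_ids)
            one_rep = cv.FoldPlan(plan.animal_ids, plan.k, 1, plan.seed,
                                  [plan.folds[rep]])
            cfg = krr.MCMCConfig(base.burn_in, base.draws, base.thin,
                                 seed=_seed(master_seed, 106, gidx, rep))
            rr = cv.run_cv(km, y, one_rep, mcmc=cfg,
                           region_name=f"{name}-IGR").records
            rr["replicate"] = rep
            recs.append(rr)
        frames.append(pd.concat(recs, ignore_index=True))
    return pd.concat(frames, ignore_index=True)
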