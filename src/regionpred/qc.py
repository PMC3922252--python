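"""Genotype editing and Bernoulli imputation.

Editing rules follow common SNP-chip preprocessing with deliberately literal
boundary semantics: SNPs with call rate <= ``call_rate_min`` or minor allele
frequency <= ``maf_min`` are removed (boundary values removed), while animals
are removed only when *strictly fewer* than ``genotyped_min`` of their SNPs
are genotyped (boundary values retained). Many toolchains use the opposite
convention, so both are documented here and fixed.

Missing genotypes are imputed locus by locus by drawing two alleles from a
Bernoulli distribution at the locus's observed allele frequency, which
assumes Hardy-Weinberg and linkage equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["QCReport", "filter_snps", "filter_animals", "impute_bernoulli", "run_qc"]


@dataclass
class QCReport:
    n_snps_in: int = 0
    n_removed_call_rate: int = 0
    n_removed_maf: int = 0
    n_snps_out: int = 0
    n_animals_in: int = 0
    n_animals_removed: int = 0
    n_animals_out: int = 0
    removed_snp_ids: list = field(default_factory=list)
    removed_animal_ids: list = field(default_factory=list)
    imputation_frequencies: np.ndarray | None = None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\n")
            fh.write(f"snps_in\t{self.n_snps_in}\n")
            fh.write(f"snps_removed_call_rate\t{self.n_removed_call_rate}\n")
            fh.write(f"snps_removed_maf\t{self.n_removed_maf}\n")
            fh.write(f"snps_out\t{self.n_snps_out}\n")
            fh.write(f"animals_in\t{self.n_animals_in}\n")
            fh.write(f"animals_removed\t{self.n_animals_removed}\n")
            fh.write(f"animals_out\t{self.n_animals_out}\n")


def filter_snps(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs with call rate <= call_rate_min or MAF <= maf_min.

    MAF is computed on non-missing dosages over all input animals. A SNP is
    retained iff call rate > call_rate_min AND MAF > maf_min; retained-SNP
    order is preserved.
    """
    if not (0.0 <= call_rate_min <= 1.0 and 0.0 <= maf_min <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    if genotypes.n_snps == 0 or genotypes.n_animals == 0:
        raise ValueError("empty genotype matrix")
    cr = genotypes.call_rates()
    maf = genotypes.minor_allele_frequencies()
    fail_cr = cr <= call_rate_min
    # all-missing loci have undefined MAF; they already fail the call-rate filter
    fail_maf = np.where(np.isnan(maf), True, maf <= maf_min)
    keep = ~(fail_cr | fail_maf)
    report = QCReport(
        n_snps_in=genotypes.n_snps,
        n_removed_call_rate=int(fail_cr.sum()),
        n_removed_maf=int((fail_maf & ~fail_cr).sum()),
        n_snps_out=int(keep.sum()),
        n_animals_in=genotypes.n_animals,
        n_animals_out=genotypes.n_animals,
        removed_snp_ids=[s for s, k in zip(genotypes.snp_ids, keep) if not k],
    )
    return genotypes.subset(snp_mask=keep), report


def filter_animals(
    genotypes: GenotypeMatrix,
    genotyped_min: float = 0.90,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove animals with strictly fewer than ``genotyped_min`` of SNPs called."""
    if not (0.0 <= genotyped_min <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    frac = genotypes.animal_call_rates()
    keep = frac >= genotyped_min
    if not keep.any():
        raise ValueError("animal call-rate filter removed every animal")
    report = QCReport(
        n_snps_in=genotypes.n_snps,
        n_snps_out=genotypes.n_snps,
        n_animals_in=genotypes.n_animals,
        n_animals_removed=int((~keep).sum()),
        n_animals_out=int(keep.sum()),
        removed_animal_ids=[a for a, k in zip(genotypes.animal_ids, keep) if not k],
    )
    return genotypes.subset(animal_mask=keep), report


def impute_bernoulli(genotypes: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Replace each missing dosage by the sum of two Bernoulli(p_hat_j) draws.

    p_hat_j is the locus's observed reference-allele frequency on the current
    matrix. Draws consume the RNG in locus-major, animal-minor order so that
    imputation is reproducible for a seed. Raises on an all-missing locus.
    """
    p = genotypes.allele_frequencies()
    if np.isnan(p).any():
        bad = genotypes.snp_ids[int(np.flatnonzero(np.isnan(p))[0])]
        raise ValueError(f"locus {bad} has no observed genotypes; frequency undefined")
    rng = np.random.default_rng(seed)
    out = genotypes.copy()
    miss = np.isnan(out.dosages)
    for j in np.flatnonzero(miss.any(axis=0)):
        rows = np.flatnonzero(miss[:, j])
        out.dosages[rows, j] = rng.binomial(2, p[j], size=rows.size)
    return out


def run_qc(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    genotyped_min: float = 0.90,
    seed: int = 0,
) -> tuple[GenotypeMatrix, QCReport]:
    """SNP filters on the full input, then the animal filter, then imputation.

    Call rate and MAF are computed once on the full input matrix; allele
    frequencies used for imputation are recomputed on the retained matrix.
    """
    g1, rep1 = filter_snps(genotypes, call_rate_min, maf_min)
    g2, rep2 = filter_animals(g1, genotyped_min)
    g3 = impute_bernoulli(g2, seed=seed)
    report = QCReport(
        n_snps_in=rep1.n_snps_in,
        n_removed_call_rate=rep1.n_removed_call_rate,
        n_removed_maf=rep1.n_removed_maf,
        n_snps_out=rep1.n_snps_out,
        n_animals_in=rep2.n_animals_in,
        n_animals_removed=rep2.n_animals_removed,
        n_animals_out=rep2.n_animals_out,
        removed_snp_ids=rep1.removed_snp_ids,
        removed_animal_ids=rep2.removed_animal_ids,
        imputation_frequencies=g2.allele_frequencies(),
    )
    return g3, report
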