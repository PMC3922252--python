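"""Additive genomic relationship kernel (VanRaden G) over SNP subsets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["KernelMatrix", "vanraden_g", "read_kernel_tsv"]


@dataclass
class KernelMatrix:
    """Symmetric n x n relationship matrix with provenance."""

    values: np.ndarray
    animal_ids: list[str]
    source: str = ""
    n_snps: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape inconsistent with animal ids")
        if not np.isfinite(self.values).all():
            raise ValueError("kernel contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kernel is not symmetric")

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.animal_ids, columns=self.animal_ids)
        df.to_csv(path, sep="\t", index_label="animal_id")


def read_kernel_tsv(path) -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KernelMatrix(df.to_numpy(), list(df.index), source=str(path))


def vanraden_g(
    genotypes: GenotypeMatrix,
    snp_subset=None,
    drop_monomorphic: bool = False,
) -> KernelMatrix:
    """G = W W' / m over the m subset SNPs.

    W standardizes dosages to (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)) with p_j
    the allele frequency observed over *all* animals in the matrix (training
    and testing together when the matrix spans both; the resulting mild
    information leakage is a property of in-sample centering, not of any
    particular split). K is taken equal to G: any proportionality constant is
    absorbed by the regression's coefficient variance.

    Monomorphic subset SNPs raise (undefined standardization) unless
    ``drop_monomorphic`` is set, in which case they are excluded and counted.
    """
    if snp_subset is None:
        idx = np.arange(genotypes.n_snps)
        name = "ALL"
    else:
        if hasattr(snp_subset, "snp_ids"):  # MatchedIGRSample
            name = f"{snp_subset.source_region}-matched-IGR"
            snp_subset = snp_subset.snp_ids
        else:
            name = "subset"
        idx = genotypes.snp_indices(sorted(snp_subset))
    X = genotypes.dosages[:, idx]
    if np.isnan(X).any():
        raise ValueError("kernel requires complete (imputed) genotypes")
    p = X.mean(axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        if not drop_monomorphic:
            bad = genotypes.snp_ids[int(idx[np.flatnonzero(mono)[0]])]
            raise ValueError(f"monomorphic SNP in kernel subset: {bad}")
        X = X[:, ~mono]
        p = p[~mono]
    m = X.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs left for the kernel")
    W = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    G = (W @ W.T) / m
    G = (G + G.T) / 2.0  # enforce exact symmetry against float round-off
    return KernelMatrix(G, list(genotypes.animal_ids), source=name, n_snps=m)
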