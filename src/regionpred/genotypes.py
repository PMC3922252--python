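"""Genotype dosage matrix container and file I/O.

Dosages are coded 0 for one homozygote, 1 for heterozygotes and 2 for the
alternative homozygote; missing entries are NaN. The reference allele whose
count a dosage reports is the one whose frequency ``allele_frequencies``
returns, i.e. dosage / 2 averaged over non-missing animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_dosage_tsv", "read_vcf"]


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix with SNP genomic coordinates.

    Parameters
    ----------
    animal_ids
        Length-n animal identifiers.
    snp_ids
        Length-p SNP identifiers.
    chrom, pos
        Per-SNP chromosome name and 1-based physical position. Positions must
        be strictly increasing within a chromosome.
    dosages
        Float array of shape (n, p) with entries in {0, 1, 2} or NaN.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray
    _snp_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if len(self.animal_ids) != n or len(self.snp_ids) != p:
            raise ValueError("id lists inconsistent with dosage shape")
        if len(self.chrom) != p or len(self.pos) != p:
            raise ValueError("coordinate arrays inconsistent with dosage shape")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        for c in pd.unique(self.chrom):
            pc = self.pos[self.chrom == c]
            if np.any(np.diff(pc) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_indices(self, snp_ids) -> np.ndarray:
        return np.array([self._snp_index[s] for s in snp_ids], dtype=np.intp)

    def call_rates(self) -> np.ndarray:
        """Per-SNP fraction of animals with a non-missing genotype."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def animal_call_rates(self) -> np.ndarray:
        """Per-animal fraction of SNPs genotyped."""
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def allele_frequencies(self) -> np.ndarray:
        """Observed reference-allele frequency per SNP over non-missing calls.

        All-missing loci yield NaN.
        """
        counts = (~np.isnan(self.dosages)).sum(axis=0).astype(float)
        sums = np.nansum(self.dosages, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / counts, np.nan) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypeMatrix":
        am = np.arange(self.n_animals) if animal_mask is None else np.flatnonzero(np.asarray(animal_mask))
        sm = np.arange(self.n_snps) if snp_mask is None else np.flatnonzero(np.asarray(snp_mask))
        return GenotypeMatrix(
            [self.animal_ids[i] for i in am],
            [self.snp_ids[j] for j in sm],
            self.chrom[sm],
            self.pos[sm],
            self.dosages[np.ix_(am, sm)],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.animal_ids), list(self.snp_ids),
            self.chrom.copy(), self.pos.copy(), self.dosages.copy(),
        )

    # ---------------------------------------------------------------- I/O

    def to_dosage_tsv(self, path) -> None:
        """Write animals x SNPs dosage TSV (NA for missing), plus coordinates
        in two header-adjacent rows (#chrom / #pos)."""
        with open(path, "w") as fh:
            fh.write("animal_id\t" + "\t".join(self.snp_ids) + "\n")
            fh.write("#chrom\t" + "\t".join(map(str, self.chrom)) + "\n")
            fh.write("#pos\t" + "\t".join(map(str, self.pos)) + "\n")
            for i, aid in enumerate(self.animal_ids):
                row = self.dosages[i]
                vals = ["NA" if np.isnan(v) else str(int(v)) for v in row]
                fh.write(aid + "\t" + "\t".join(vals) + "\n")

    def to_vcf(self, path) -> None:
        """Write an uncompressed VCF 4.2 with GT fields ("./." for missing).

        Dosage counts the ALT allele so that ``read_vcf`` round-trips.
        """
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for c in dict.fromkeys(self.chrom):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.animal_ids) + "\n")
            gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            for j, sid in enumerate(self.snp_ids):
                gts = [
                    "./." if np.isnan(v) else gt_code[v]
                    for v in self.dosages[:, j]
                ]
                fh.write(f"{self.chrom[j]}\t{self.pos[j]}\t{sid}\tA\tC\t.\t.\t.\tGT\t"
                         + "\t".join(gts) + "\n")


def read_dosage_tsv(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        snp_ids = header[1:]
        chrom_row = fh.readline().rstrip("\n").split("\t")
        pos_row = fh.readline().rstrip("\n").split("\t")
        if chrom_row[0] != "#chrom" or pos_row[0] != "#pos":
            raise ValueError("dosage TSV missing #chrom/#pos coordinate rows")
        chrom = np.array(chrom_row[1:], dtype=object)
        pos = np.array(pos_row[1:], dtype=np.int64)
        animal_ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            animal_ids.append(parts[0])
            rows.append([np.nan if v == "NA" else float(v) for v in parts[1:]])
    return GenotypeMatrix(animal_ids, snp_ids, chrom, pos, np.array(rows))


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into ALT-dosage coding."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animal_ids = list(vcf.samples)
    snp_ids, chrom, pos, cols = [], [], [], []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        gts = var.genotype.array()[:, :2].astype(float)
        gts[gts < 0] = np.nan
        cols.append(gts.sum(axis=1))
    vcf.close()
    return GenotypeMatrix(animal_ids, snp_ids, np.array(chrom, dtype=object),
                          np.array(pos), np.column_stack(cols))
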