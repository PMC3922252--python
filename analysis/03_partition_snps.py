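#!/usr/bin/env python
"""Assign QC-passed SNPs to the five nested region classes.

Reads the simulated GFF3 annotation, partitions the retained SNPs into CDS,
Exons (CDS + UTR), Genes (CDS + UTR + introns), Genes1kb (genes plus 1 kb
flanks) and IGR (the complement), checks the nesting/complement algebra, and
writes one SNP-id list and one BED file per class.
"""

import os

from regionpred.annotate import build_partition
from regionpred.genotypes import read_dosage_tsv

DATA = os.path.join(os.path.dirname(__file__), "..", "results", "data")


def main():
    geno = read_dosage_tsv(os.path.join(DATA, "dosages_clean.tsv"))
    snp_map = list(zip(geno.snp_ids, geno.chrom, geno.pos))
    part = build_partition(snp_map, os.path.join(DATA, "genome.gff3"))
    part.validate(geno.snp_ids)
    out = os.path.join(DATA, "regions")
    part.write(out)
    part.write_bed(out, snp_map)
    print(f"{'region':<10}{'SNPs':>8}")
    for name in ("IGR", "Genes1kb", "Genes", "Exons", "CDS"):
        print(f"{name:<10}{len(part[name]):>8}")


if __name__ == "__main__":
    main()
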