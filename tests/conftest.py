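import numpy as np
import pytest

from regionpred import annotate, simulate


@pytest.fixture(scope="session")
def small_genome():
    """1 Mb single-chromosome genome, 5 genes, ~1000 SNPs."""
    return simulate.simulate_genome(1, 1_000_000, 5, 1e-3, seed=1)


@pytest.fixture(scope="session")
def small_partition(small_genome):
    return annotate.build_partition(small_genome.snp_map, small_genome)


@pytest.fixture(scope="session")
def small_genotypes(small_genome):
    return simulate.simulate_genotypes(120, small_genome.snp_map, seed=2)


def naive_partition(snp_map, genome, flank_bp=1000):
    """O(SNPs x intervals) membership scan, the independent partition oracle."""
    sets = {k: set() for k in ("CDS", "Exons", "Genes", "Genes1kb", "IGR")}
    for sid, chrom, pos in snp_map:
        in_cds = in_exon = in_gene = in_flank = False
        for g in genome.genes:
            if g.chrom != chrom:
                continue
            if g.start - flank_bp <= pos <= g.end + flank_bp:
                in_flank = True
            if g.start <= pos <= g.end:
                in_gene = True
            for s, e in g.exons:
                if s <= pos <= e:
                    in_exon = True
            for s, e in g.cds:
                if s <= pos <= e:
                    in_cds = True
        if in_cds:
            sets["CDS"].add(sid)
        if in_cds or in_exon:
            sets["Exons"].add(sid)
        if in_cds or in_exon or in_gene:
            sets["Genes"].add(sid)
        if in_cds or in_exon or in_gene or in_flank:
            sets["Genes1kb"].add(sid)
        if not (in_cds or in_exon or in_gene or in_flank):
            sets["IGR"].add(sid)
    return {k: frozenset(v) for k, v in sets.items()}
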