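"""Synthetic genomes, genotypes, systematic effects and phenotypes.

The generator emulates the statistical structure of a commercial broiler
SNP-chip study: biallelic SNPs at Hardy-Weinberg proportions, nested gene
models (CDS within exons within genes, 1 kb regulatory flanks), additive
trait architectures either concentrated in a chosen annotation class or
spread genome-wide, a many-level random systematic factor in which most
levels carry one or two animals, and Gaussian residual noise calibrated to a
target narrow-sense heritability.

Loci are in linkage equilibrium by default (independent per-SNP draws); an
optional haplotype-copying mode introduces LD between nearby markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "GeneModel",
    "SimulatedGenome",
    "SystematicEffects",
    "TraitArchitecture",
    "TruthRecord",
    "simulate_genome",
    "simulate_genotypes",
    "simulate_phenotypes",
    "inject_missingness",
]

REGION_CLASSES = ("CDS", "Exons", "Genes", "Genes1kb", "IGR")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with exon and CDS sub-intervals (1-based, closed).

    UTR is implied as exon minus CDS; introns as gene minus exons.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for name, ivs, outer in (("exon", self.exons, (self.start, self.end)),):
            prev_end = 0
            for s, e in ivs:
                if s > e or s < outer[0] or e > outer[1]:
                    raise ValueError(f"invalid {name} interval ({s},{e}) in {self.gene_id}")
                if s <= prev_end:
                    raise ValueError(f"{name} intervals overlap/unsorted in {self.gene_id}")
                prev_end = e
        for s, e in self.cds:
            if s > e or not any(s >= es and e <= ee for es, ee in self.exons):
                raise ValueError(f"CDS interval ({s},{e}) not within an exon of {self.gene_id}")


@dataclass
class SimulatedGenome:
    """Chromosome lengths, gene models and a SNP map."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]
    snp_map: list[tuple[str, str, int]]  # (snp_id, chrom, pos)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for sid, c, p in self.snp_map:
            if c not in lengths or not (1 <= p <= lengths[c]):
                raise ValueError(f"SNP {sid} at {c}:{p} outside chromosome bounds")

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def to_gff3(self, path) -> None:
        """Write gene/exon/CDS rows as GFF3 (1-based closed intervals)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, length in self.chromosomes:
                fh.write(f"##sequence-region {name} 1 {length}\n")
            for g in self.genes:
                fh.write(f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}\n")
                for k, (s, e) in enumerate(g.exons, 1):
                    fh.write(f"{g.chrom}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                             f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n")
                for k, (s, e) in enumerate(g.cds, 1):
                    fh.write(f"{g.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                             f"ID={g.gene_id}.cds{k};Parent={g.gene_id}\n")


@dataclass(frozen=True)
class SystematicEffects:
    """Many-level random factor mimicking hatch/contemporary-group effects.

    ``variance_share`` is the fraction of total phenotypic variance explained
    by the factor; level sizes are drawn so that ``singleton_frac`` of animals
    sit in levels observed once and ``doubleton_frac`` in levels observed
    twice, with the remainder in levels of 3-6 animals.
    """

    variance_share: float = 0.20
    singleton_frac: float = 0.40
    doubleton_frac: float = 0.28

    def __post_init__(self) -> None:
        if not (0.0 < self.variance_share < 1.0):
            raise ValueError("variance_share must be in (0, 1)")
        if self.singleton_frac + self.doubleton_frac > 1.0:
            raise ValueError("singleton + doubleton fractions exceed 1")


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive architecture for one trait.

    ``h2`` is narrow-sense heritability on the preadjusted scale, i.e.
    var(g) / (var(g) + var(e)) excluding systematic-effect variance from the
    denominator. ``n_causal=None`` puts effects on every SNP of the target
    class.
    """

    target_class: str = "ALL"
    h2: float = 0.30
    n_causal: int | None = None
    systematic: SystematicEffects | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        if self.target_class not in REGION_CLASSES + ("ALL",):
            raise ValueError(f"unknown target class {self.target_class!r}")
        if self.h2 == 1.0 and self.systematic is not None:
            raise ValueError("h2=1 with a nonzero systematic effect is inconsistent")


@dataclass
class TruthRecord:
    """Ground truth of one phenotype simulation."""

    genetic_values: np.ndarray           # per-animal true g
    snp_effects: pd.Series               # per-SNP true beta (0 if non-causal)
    level_of_animal: np.ndarray | None   # systematic level id per animal
    level_effects: dict | None
    realized_h2: float
    mu: float

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({
            "animal_index": np.arange(len(self.genetic_values)),
            "g_true": self.genetic_values,
            "level": self.level_of_animal if self.level_of_animal is not None else "",
        })
        df.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ genome


def simulate_genome(
    n_chrom: int = 2,
    chrom_length: int = 1_000_000,
    genes_per_chrom: int = 5,
    snp_density: float = 1e-3,
    seed: int = 0,
    flank_bp: int = 1000,
) -> SimulatedGenome:
    """Draw a genome with non-overlapping multi-exon genes and a uniform SNP map.

    Genes have >=2 exons, each exon carrying a CDS sub-interval flanked by
    UTR-like exon sequence, and neighbouring genes are separated by more than
    ``2 * flank_bp + 1`` bp so 1 kb regulatory flanks never overlap another
    gene. SNP positions are drawn uniformly at ``snp_density`` per bp.
    """
    if n_chrom < 1 or chrom_length < 1 or genes_per_chrom < 0:
        raise ValueError("chromosome/gene counts and lengths must be positive")
    if snp_density <= 0:
        raise ValueError("snp_density must be positive")
    rng = np.random.default_rng(seed)
    gap = 2 * flank_bp + 100  # minimum intergenic spacing
    chromosomes = [(f"chr{i + 1}", chrom_length) for i in range(n_chrom)]
    genes: list[GeneModel] = []
    for cname, clen in chromosomes:
        if genes_per_chrom == 0:
            continue
        slot = clen // genes_per_chrom
        gene_len_max = max(2000, min(slot - gap, slot // 2))
        for gidx in range(genes_per_chrom):
            glen = int(rng.integers(2000, gene_len_max + 1))
            lo = gidx * slot + gap // 2
            hi = (gidx + 1) * slot - gap // 2 - glen
            if hi <= lo:
                raise ValueError("chromosome too short for requested gene count")
            start = int(rng.integers(lo, hi))
            end = start + glen - 1
            n_exons = int(rng.integers(2, 5))
            # partition [start, end] into alternating exon/intron blocks
            cuts = np.linspace(start, end, 2 * n_exons, dtype=int)
            exons, cds = [], []
            for k in range(n_exons):
                es, ee = int(cuts[2 * k]), int(cuts[2 * k + 1]) - (1 if k < n_exons - 1 else 0)
                if ee <= es + 2:
                    ee = es + 3
                exons.append((es, ee))
                # CDS sits inside the exon, leaving UTR-like margins
                margin = max(1, (ee - es) // 5)
                cds.append((es + margin, ee - margin))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"{cname}_g{gidx + 1}", cname, strand,
                                   start, end, tuple(exons), tuple(cds)))
    snp_map: list[tuple[str, str, int]] = []
    for cname, clen in chromosomes:
        n_snp = int(round(clen * snp_density))
        pos = np.sort(rng.choice(np.arange(1, clen + 1), size=n_snp, replace=False))
        for p in pos:
            snp_map.append((f"{cname}_s{int(p)}", cname, int(p)))
    return SimulatedGenome(chromosomes, genes, snp_map)


# --------------------------------------------------------------- genotypes


def simulate_genotypes(
    n_animals: int,
    snp_map: list[tuple[str, str, int]],
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    ld_mode: bool = False,
    n_founder_haplotypes: int = 20,
    switch_rate: float = 0.01,
) -> GenotypeMatrix:
    """Sample dosages at Hardy-Weinberg proportions, loci independent.

    Per locus an allele frequency p_j ~ Uniform(maf_range) is drawn and each
    animal's dosage is Binomial(2, p_j). With ``ld_mode`` animals instead copy
    two mosaic haplotypes from a founder pool, switching template with
    probability ``switch_rate`` per marker, which induces local LD while
    preserving HWE marginally.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if n_animals < 2:
        raise ValueError("need at least 2 animals")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=len(snp_map))
    if not ld_mode:
        dosages = rng.binomial(2, p, size=(n_animals, len(snp_map))).astype(float)
    else:
        m = len(snp_map)
        founders = (rng.random((n_founder_haplotypes, m)) < p).astype(np.int8)
        dosages = np.zeros((n_animals, m))
        for i in range(n_animals):
            for _ in range(2):
                tpl = int(rng.integers(n_founder_haplotypes))
                switch = rng.random(m) < switch_rate
                hap = np.empty(m, dtype=np.int8)
                for j in range(m):
                    if switch[j]:
                        tpl = int(rng.integers(n_founder_haplotypes))
                    hap[j] = founders[tpl, j]
                dosages[i] += hap
    snp_ids = [s[0] for s in snp_map]
    chrom = np.array([s[1] for s in snp_map], dtype=object)
    pos = np.array([s[2] for s in snp_map])
    return GenotypeMatrix([f"a{i + 1}" for i in range(n_animals)],
                          snp_ids, chrom, pos, dosages)


# -------------------------------------------------------------- phenotypes


def _assign_levels(n: int, spec: SystematicEffects, rng) -> np.ndarray:
    """Assign animals to factor levels hitting the target singleton/doubleton
    animal fractions; remaining animals fill levels of size 3-6."""
    n_single = int(round(spec.singleton_frac * n))
    n_double = int(round(spec.doubleton_frac * n / 2.0)) * 2
    sizes = [1] * n_single + [2] * (n_double // 2)
    left = n - n_single - n_double
    while left > 0:
        s = min(int(rng.integers(3, 7)), left)
        sizes.append(s)
        left -= s
    labels = np.concatenate([np.full(s, k) for k, s in enumerate(sizes)])
    rng.shuffle(labels)
    return labels


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    partition,
    architecture: TraitArchitecture,
    seed: int = 0,
    mu: float = 0.0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate y = mu + s + g + e for one trait.

    g = X_c beta over the causal SNPs (centered dosages, beta ~ N(0, 1));
    residual variance is scaled so var(g)/(var(g)+var(e)) hits the target
    heritability (systematic variance excluded from the denominator, matching
    a preadjusted-phenotype analysis). ``partition`` maps region-class names
    to SNP-id sets and may be None when target_class is "ALL".

    Returns a phenotype table (animal_id, y, level) and the truth record.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_animals
    if architecture.target_class == "ALL":
        pool = list(genotypes.snp_ids)
    else:
        regions = partition.regions if hasattr(partition, "regions") else partition
        pool = sorted(regions[architecture.target_class])
        if not pool:
            raise ValueError(f"target class {architecture.target_class} is empty")
    if architecture.n_causal is not None:
        if architecture.n_causal > len(pool):
            raise ValueError("n_causal exceeds the size of the target class")
        pool = sorted(rng.choice(pool, size=architecture.n_causal, replace=False))
    idx = genotypes.snp_indices(pool)
    X = genotypes.dosages[:, idx]
    if np.isnan(X).any():
        raise ValueError("phenotype simulation requires complete genotypes")
    Xc = X - X.mean(axis=0)
    beta = rng.normal(0.0, 1.0, size=len(pool))
    g = Xc @ beta
    h2 = architecture.h2
    # rescale effects so the trait sits on a standardized scale: var(g) = h2
    # and var(e) = 1 - h2, i.e. unit phenotypic variance before systematic
    # effects. Weakly informative unit-scale variance priors downstream
    # presume phenotypes of roughly this magnitude.
    if h2 == 0.0:
        g = np.zeros(n)
        beta[:] = 0.0
        var_g = 0.0
        var_e = 1.0
    else:
        raw = float(np.var(g))
        scale = np.sqrt(h2 / raw)
        g *= scale
        beta *= scale
        var_g = h2
        var_e = 1.0 - h2
    e = rng.normal(0.0, np.sqrt(var_e), size=n) if var_e > 0 else np.zeros(n)

    levels = None
    level_effects = None
    s = np.zeros(n)
    if architecture.systematic is not None:
        spec = architecture.systematic
        levels = _assign_levels(n, spec, rng)
        base = var_g + var_e if var_g + var_e > 0 else 1.0
        var_s = spec.variance_share * base / (1.0 - spec.variance_share)
        uniq = np.unique(levels)
        eff = rng.normal(0.0, np.sqrt(var_s), size=len(uniq))
        level_effects = dict(zip(uniq.tolist(), eff.tolist()))
        s = eff[np.searchsorted(uniq, levels)]

    y = mu + s + g + e
    denom = var_g + float(np.var(e))
    realized = var_g / denom if denom > 0 else 0.0
    effects = pd.Series(0.0, index=genotypes.snp_ids)
    effects.iloc[idx] = beta
    pheno = pd.DataFrame({
        "animal_id": genotypes.animal_ids,
        "y": y,
        "level": [f"L{v}" for v in levels] if levels is not None else ["L0"] * n,
    })
    truth = TruthRecord(g, effects,
                        np.array([f"L{v}" for v in levels]) if levels is not None else None,
                        level_effects, realized, mu)
    return pheno, truth


# ------------------------------------------------------------- missingness


def inject_missingness(
    genotypes: GenotypeMatrix,
    snp_rates=0.0,
    animal_rates=0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Set entries to missing: entry (i, j) is dropped with probability
    1 - (1 - snp_rate_j)(1 - animal_rate_i). Rates may be scalars or arrays."""
    snp_rates = np.broadcast_to(np.asarray(snp_rates, dtype=float), (genotypes.n_snps,))
    animal_rates = np.broadcast_to(np.asarray(animal_rates, dtype=float), (genotypes.n_animals,))
    if (snp_rates < 0).any() or (snp_rates >= 1).any() or \
            (animal_rates < 0).any() or (animal_rates >= 1).any():
        raise ValueError("missingness rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    keep = (1.0 - animal_rates)[:, None] * (1.0 - snp_rates)[None, :]
    drop = rng.random(genotypes.dosages.shape) >= keep
    out = genotypes.copy()
    out.dosages[drop] = np.nan
    return out
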