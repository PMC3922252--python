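# regionpred

Where in the genome does the predictive signal for a complex trait live?
`regionpred` is an analysis pipeline for answering that question with
annotation-partitioned genomic prediction, built around the workflow used in
commercial-poultry genomic evaluation: SNPs are assigned to five nested
annotation classes — **CDS**, **Exons** (CDS + UTR), **Genes** (CDS + UTR +
introns), **Genes1kb** (genes ± 1 kb regulatory flanks) and **IGR** (the
intergenic complement) — and each class is scored by how well a genomic
relationship kernel built from its SNPs alone predicts phenotypes of
held-out animals, against a random intergenic SNP set of equal size as the
control and the all-SNP kernel as the benchmark.

The core model is a **kernel Bayesian ridge regression** fitted by Gibbs
sampling:

    y_R = μ1 + Kα + ε,   ε ~ N(0, Iσ²_ε),   α ~ N(0, Iσ²_α)

where `y_R` are phenotypes preadjusted for a many-level random systematic
factor (EM-REML BLUPs), `K = G` is the VanRaden genomic relationship matrix
of the region's SNPs (`G = WW'/m`, `W` centered/standardized dosages), and
the implied penalty is `λ‖α‖²` with `λ = σ²_ε/σ²_α` (the kernel is not in
the penalty, unlike RKHS regression). Both variances carry scaled-inverse-χ²
(ν = 3, S = 1) priors. Regions are compared by cross-validated predictive
correlation `cor(y_R, k_i'α̂)` (10 folds × 15 replicates) and by Ward
clustering of their predicted genetic-value vectors `ĝ = Kα̂`.

Real 600K-chip data are proprietary, so a first-class synthetic-data module
generates annotated genomes, HWE genotypes, systematic-effect structures
(~40% singleton levels) and trait architectures with chosen heritabilities —
everything downstream is testable end to end. See `docs/methods.md` for the
model, algorithms and design choices.

## Layout

```
src/regionpred/     library: simulate, qc, annotate, kernel, preadjust,
                    krr (Gibbs sampler), cv, cluster, benchmarks, experiment
analysis/           numbered drivers reproducing the study design
results/            tables, trees and figures the drivers write
scripts/acceptance.py   recomputes the headline recovery numbers
```

A `regionpred` console command exposes each stage
(`simulate | qc | partition | kernel | preadjust | fit | cv | cluster | all`).

## Worked example

Running the drivers in order regenerates everything under `results/`:

```bash
python analysis/01_simulate_study.py      # genome, genotypes, 3 traits
python analysis/02_qc_impute.py           # editing rules + imputation
python analysis/03_partition_snps.py      # five nested region classes
python analysis/04_preadjust.py           # EM-REML preadjustment
python analysis/05_cross_validate.py      # replicated 10-fold CV per region
python analysis/06_cluster_regions.py     # Ward dendrograms of ĝ vectors
python analysis/07_heritability_recovery.py
```

Step 01 simulates 250 animals × 2,000 SNPs (region sizes: CDS 147,
Exons 241, Genes 418, Genes1kb 466, IGR 1,534) and three standardized
traits: `bw` (genome-wide effects, h² = 0.30), `bm` (effects confined to
genic SNPs, h² = 0.33) and `hhp` (genome-wide, h² = 0.19). Step 05 then
prints, for the genic-architecture trait:

```
=== bm ===
  region   mean    q25  median   q75
   Exons  0.191  0.091   0.224 0.300
Genes1kb  0.182  0.073   0.211 0.312
   Genes  0.181  0.072   0.230 0.308
     CDS  0.139  0.012   0.155 0.294
     ALL  0.085 -0.012   0.056 0.212
     IGR -0.022 -0.138  -0.002 0.104
CDS-IGR  -0.033 -0.150  -0.066 0.098
```

Mean fold correlations for every genic class clearly exceed both full IGR
and the size-matched IGR controls (`*-IGR`) — when the causal variants sit
in genes, genic SNPs carry the predictive signal and equally many random
intergenic SNPs carry essentially none. For the two genome-wide traits the
classes separate much less and their ordering is unstable at this
demonstration scale (five fold-assignment replicates, 250 animals), as
expected when every class tags a diffuse infinitesimal signal. Step 06 confirms the same
structure geometrically — for every trait the Ward tree's top split
separates the four genic kernels from {IGR, ALL}, e.g.

```
bm: top split ['CDS', 'Exons', 'Genes', 'Genes1kb'] | ['ALL', 'IGR']
```

and step 07 reports the genomic variance ratio recovered from n = 1,000,
p = 5,000 genome-wide simulations:

```
bw : simulated 0.30 -> recovered 0.258 (range 0.223-0.293 over 10 replicates)
bm : simulated 0.33 -> recovered 0.268 (range 0.233-0.306 over 10 replicates)
hhp: simulated 0.19 -> recovered 0.225 (range 0.192-0.263 over 10 replicates)
```

The ratio is deliberately reported as the model defines it,
`var(Kα)/(var(Kα)+σ²_ε)`; in an unrelated HWE population it is weakly
identified and mildly attenuated/inflated around the truth — see
`docs/methods.md` for the spectral argument.

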