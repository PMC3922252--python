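# Methods

## The problem

Whole-genome prediction regresses phenotypes on dense SNP genotypes to
predict additive genetic values of selection candidates. A natural question
is where the predictive signal resides: in protein-coding sequence, in
genes at large, in nearby putative regulatory sequence, or spread through
intergenic space. This package implements a complete pipeline for asking
that question: SNPs are assigned to five nested annotation classes — CDS,
Exons (CDS + UTR), Genes (CDS + UTR + introns), Genes1kb (genes plus 1 kb
upstream/downstream flanks) and IGR (the intergenic complement) — a
genomic-relationship kernel is built per class, a Bayesian kernel ridge
regression is fitted to phenotypes precorrected for systematic effects, and
classes are compared by cross-validated predictive correlation and by
clustering of their predicted genetic values. Each genic class is compared
against a random intergenic SNP set of equal size, so that differences in
marker count do not masquerade as differences in functional enrichment.

## Model

For animal *i* with preadjusted phenotype *y_Ri*:

    y_R = mu 1 + K alpha + eps,
    eps ~ N(0, I sigma2_e),  alpha ~ N(0, I sigma2_a)

with K = G, the VanRaden genomic relationship matrix computed from the
region's SNPs: G = W W' / m, where column *j* of W is
(x_j - 2 p_j) / sqrt(2 p_j (1 - p_j)) and p_j is the in-sample allele
frequency. The coefficient vector alpha has length n (number of animals),
so the prior-induced penalty is lambda ||alpha||^2 with
lambda = sigma2_e / sigma2_a. This differs from the RKHS formulation, whose
penalty is lambda ||K alpha||^2_H; here the kernel enters the regression
but not the penalty. Priors: flat on mu; scaled inverse chi-square with
nu = 3 degrees of freedom and scale S = 1 on both variances. The unit prior
scale presumes phenotypes of roughly unit variance — the synthetic traits
are generated on that scale (below), as standardized real traits would be.

### Gibbs sampler

Full conditionals are sampled in the fixed order mu, alpha, sigma2_a,
sigma2_e:

* mu | rest ~ N(mean(y_R - K alpha), sigma2_e / n)
* alpha | rest ~ N(C^-1 K'(y_R - mu 1)/sigma2_e, C^-1),
  C = K'K/sigma2_e + I/sigma2_a, drawn as one block
* sigma2_a | rest ~ scaled-inv-chi2(nu + n, (alpha'alpha + nu S)/(nu + n))
* sigma2_e | rest ~ scaled-inv-chi2(nu + n, (e'e + nu S)/(nu + n))

The default implementation eigendecomposes K = U D U' once and works on
beta = U'alpha, in which basis C is diagonal; a sweep then costs O(n)
rather than O(n^3), which is what makes 10,000-60,000 sweeps inside
replicated cross-validation practical. A direct Cholesky sampler is kept
and tested to produce distributionally identical chains. Chains are
initialized at mu = mean(y_R), alpha = 0 and both variances at
var(y_R)/2. Two presets exist: "paper" (burn-in 20,000; 40,000 draws
thinned at 10, retaining exactly 4,000 samples) and "reduced" (burn-in
2,000; 8,000 draws thinned at 10), the default inside cross-validation and
tests. Convergence is monitored quantitatively with autocorrelation-based
effective sample sizes and a split-chain potential-scale-reduction factor
rather than by eye.

With the variance components held fixed the sampler's stationary mean of
alpha equals the closed-form ridge estimator
(K'K + lambda I)^-1 K'(y_R - mu 1); this oracle equivalence is asserted in
the test suite within Monte-Carlo error.

### Genomic variance ratio

At each retained draw the sampler records var(K alpha) (sample variance
across animals) and the ratio var(K alpha) / (var(K alpha) + sigma2_e) —
the model's analogue of narrow-sense heritability on the preadjusted scale.
An important property, verified here by comparing the sampler against a
brute-force grid integration of the marginalized posterior: when animals
are mutually unrelated (independent HWE genotypes) the likelihood for this
ratio is nearly flat, because the eigenvalue spectrum of G is a narrow
Marchenko-Pastur bulk. Two consequences follow. First, with moderate p/n
(e.g. 5) the ratio is attenuated: the model's implied genetic covariance is
K^2 sigma2_a while the simulated genetic covariance is proportional to K,
and fitting d^2 sigma2_a to d sigma2_g across the spectrum shrinks the
recovered ratio by roughly E[d^3]E[d^2]/E[d^4] (about 0.8 at p/n = 5).
Second, with large p/n the likelihood carries almost no information and the
unit-scale prior dominates. Recovery experiments at n = 1,000, p = 5,000
therefore return ratios a few hundredths below a simulated 0.30 and a few
hundredths above a simulated 0.19. In real livestock data family structure
widens the spectrum of G and identifies the ratio much more strongly; the
synthetic unrelated-population setting is the conservative case.

## Preadjustment

Systematic effects (hatch, sex, contemporary group) enter as a one-way
random factor: y = mu + s_l + e, s_l ~ N(0, sigma2_s). Because most levels
are observed once or twice, fixed-effect correction would be degenerate;
the random-effects model shrinks level estimates by
n_l sigma2_s / (n_l sigma2_s + sigma2_e). Variance components are estimated
by EM-REML on the mixed-model equations, exploiting their arrow structure
for O(L) iterations, with two standard safeguards: Aitken extrapolation on
trajectory snapshots (accepted only when the REML objective does not
decrease) where EM's linear rate approaches one, and explicit comparison
against the profiled sigma2_s = 0 solution to terminate boundary cases
exactly. Convergence: relative parameter change below 1e-8 or 10,000
iterations. The balanced-design closed form ((MSB - MSW)/r, MSW) serves as
the test oracle. The preadjusted phenotype is
y_R = y - mu_hat - s_hat(level).

Two documented biases are accepted rather than corrected: the genetic
signal is partly absorbed into level means (two-step shrinkage bias), and
with singleton-heavy designs sigma2_s itself is weakly identified — in one
synthetic trait of the demonstration analysis the REML estimate hits the
zero boundary even though the generating variance share was 0.20.
Preadjustment is performed once on all animals; fold-level refitting is not
done, and the (mild) resulting leakage is a known property of the two-step
design. Likewise kernels use in-sample allele frequencies over all animals,
matching the single n x n kernel indexed by all observed genotypes.

## Cross-validation

Animals are randomly partitioned into 10 disjoint folds (sizes differing by
at most one); each fold serves as the test set once; the whole assignment
is replicated 15 times. Within a fold the sampler sees only the train x
train block of K and the held-out animals are scored by
g_hat_test = K[test, train] alpha_hat; predictive ability is the Pearson
correlation cor(y_R[test], g_hat_test). Matched intergenic controls are
resampled once per (genic region, replicate), so control boxplots also
carry control-sampling uncertainty. Every (replicate, fold) cell derives
its seed from the master seed via SeedSequence spawn keys and is
reproducible in isolation. Fold summaries of train x test relatedness
(mean/median of off-diagonal G) are reported alongside; with in-sample
centering these sit near or slightly below zero.

## Clustering of predicted genetic values

For each trait the per-region g_hat = K alpha_hat vectors (full-data fits)
are compared by pairwise Euclidean norms and agglomerated under Ward's
minimum-variance criterion: each merge is the pair whose fusion minimally
increases total within-cluster sum of squares. The implementation applies
the Lance-Williams recurrence for Ward on the SSE-increase scale
(singleton pairs initialize at d^2/2), with ties broken lexicographically
on cluster labels so dendrograms are deterministic; with at most ~10 region
leaves the O(L^3) naive agglomeration is ample. Heights are directly
comparable to a brute-force implementation that recomputes within-cluster
SSE from raw vectors, and to scipy's ward linkage via height^2/2. Trees are
serialized as ultrametric Newick (a node sits at half its merge height).

## Synthetic data

The generator emulates the statistical structure of a commercial broiler
600K-chip study at desk scale:

* **Genome**: 1-to-few chromosomes; non-overlapping genes with 2-4 exons,
  each exon carrying a CDS core with UTR-like margins; a minimum intergenic
  gap larger than twice the 1 kb flank so Genes1kb/IGR assignment is never
  ambiguous; SNPs placed uniformly (default 2 per kb).
* **Genotypes**: per locus p_j ~ Uniform(0.05, 0.5) and dosages
  Binomial(2, p_j) — Hardy-Weinberg proportions with linkage equilibrium,
  matching the assumptions of the locus-wise Bernoulli imputation. An
  optional haplotype-copying mode (founder pool, per-marker template
  switching) induces local LD; it is off by default.
* **Phenotypes**: y = mu + s + g + e with g = X_c beta over the causal
  SNPs (centered dosages, beta ~ N(0,1) rescaled). Traits are standardized:
  var(g) = h2 and var(e) = 1 - h2, so the phenotypic variance on the
  preadjusted scale is 1 and the unit-scale variance priors downstream are
  correctly calibrated. Heritability is defined excluding systematic
  variance from the denominator (the preadjusted scale). Architectures
  either spread effects genome-wide (infinitesimal-like; defaults target
  h2 = 0.30 and 0.19 for the body-weight- and egg-production-like traits)
  or confine them to one annotation class (oligogenic/enriched; h2 = 0.33
  for the breast-meat-like trait).
* **Systematic factor**: level sizes drawn so ~40% of animals sit in
  singleton levels and ~28% in doubletons, remainder in levels of 3-6;
  Gaussian level effects with a default 20% share of phenotypic variance.
  (The level-effect distribution of the real factor is unknown; Gaussian is
  assumed.)
* **Missingness**: independent per-entry dropout with per-SNP and
  per-animal rates, default ~1%, to exercise the editing and imputation
  rules.

What the generator does *not* emulate: linkage disequilibrium (by
default), family/pedigree structure, selection, population stratification,
dominance/epistasis, sex chromosomes, and genotyping error beyond
missingness. Passing tests therefore demonstrate correctness of the
machinery and directional behaviour under clean additive architectures,
not performance on structured real populations — in particular,
predictive correlations here are lower than in real livestock data, where
family relatedness carries much of the signal.

## Editing rules

Boundary semantics are deliberately literal: SNPs are removed at call rate
<= 0.95 or minor allele frequency <= 0.01 (boundary removed), animals at
genotyped fraction < 0.90 (boundary retained). Call rate and MAF are
computed once on the full input; the SNP filters apply first, then the
animal filter; allele frequencies for imputation are recomputed on the
retained matrix. Imputation draws two Bernoulli(p_hat) alleles per missing
entry in locus-major, animal-minor RNG order.

## Problem sizes used in tests and the reproduction script

Recovery experiments use n = 1,000 animals and p = 5,000 SNPs with 10
simulation replicates; region-comparison experiments use 200-300 animals
on a ~2,000-SNP annotated genome with 10-fold CV and 15 fold-assignment
replicates under the reduced chain; the demonstration analysis under
`analysis/` uses 250 animals and 5 replicates by default (a flag restores
15). These sizes were chosen as the smallest at which the directional
contrasts are comfortably resolved by the Monte-Carlo design.

## Known limitations

* The genomic variance ratio of the coefficient-penalized kernel model is
  weakly identified in unrelated populations (see above); treat it as a
  model-internal signal share, not an unbiased heritability estimator.
* Preadjustment and kernel centering both use all animals once, so
  cross-validation carries the mild two-step leakage discussed above.
* The matched-IGR comparison controls marker count but not allele-frequency
  spectrum or local SNP density.
* EM-REML handles a single random factor; crossed or nested systematic
  factors would need a general mixed-model fitter.
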