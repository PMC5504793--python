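# Methods

`treegs` re-creates, on simulated data, the complete analysis cycle of a
genomic-selection study in an open-pollinated (OP) forest-tree breeding
population: genotype QC, linkage-disequilibrium (LD) characterization with
kinship/structure corrections, LD-based effective population size, pedigree
and genomic relationship matrices, frequentist and Bayesian whole-genome
regression with cross-validated predictive ability, SNP-subset designs,
relatedness-controlled validation, and mixed-model GWAS. This note records
the models, the defaults and why they were chosen, and what the synthetic
test bed does and does not establish.

## The synthetic breeding population

The simulator (`treegs.simpop`) is a discrete-generation Wright–Fisher
forward model of diploids with random mating, no selection and no mutation.
Its defaults emulate a tropical eucalypt progeny trial: effective population
size Ne = 35–50, 11 chromosomes of 50 Mbp, 13.8k–19.5k polymorphic chip
SNPs, 24–40 OP maternal families of 500–750 genotyped trees, optional K = 2
substructure, and an additive growth trait with narrow-sense heritability
0.1–0.5 scored in a randomized complete block design (RCBD) with ~40 blocks
and ~1% missing genotype calls.

Mechanics and the reasoning behind them:

* **Recombination** is uniform at 1 cM/Mbp (Poisson crossovers, independent
  assortment between chromosomes). No linkage map is assumed; only the
  relative LD scale matters for every downstream property that is tested.
* **Marker ascertainment.** Candidate sites start at uniform-random
  frequencies in (0.05, 0.95) and drift for `4·ne` generations so LD reaches
  its drift–recombination equilibrium. Because drift fixes most
  uniformly-initialized loci, the simulator generates an oversampled
  candidate pool (8× by default) and thins it back to the requested number
  of segregating sites — mirroring the fact that genotyping chips are
  ascertained to be polymorphic. `n_markers` therefore means *retained
  polymorphic markers*.
* **Population structure.** When `fst > 0` the population descends from a
  larger ancestral stand (`ancestral_factor·ne`, default 4×) that drifts
  briefly; two islands of `ne` diploids are then founded from it and drift
  apart for `t = 2·ne·fst` generations (the small-t approximation
  Fst ≈ t/2Ne). The larger ancestral phase is deliberate: if the ancestral
  pool itself were equilibrated at `ne`, within-island coancestry would be
  as large as the island contrast and K = 2 would not be the leading axis of
  genetic structure — unlike real provenance-structured populations, where
  divergence between seed origins dominates PCA. Realized Hudson Fst lands
  within ±0.05 of the target at `fst = 0.1`.
* **OP families.** Mothers are drawn without replacement from the adult
  pool; each offspring combines a recombinant maternal gamete with a gamete
  from a random non-maternal adult of the same subpopulation (the pollen
  pool). Expected within-family additive relationship is 0.25 (maternal
  half-sibs). Genotypes are coded as minor-allele dosages 0/1/2 with
  missing-completely-at-random dropout.
* **Trait.** `n_qtl` causal loci are drawn uniformly among markers; N(0,1)
  effects are rescaled so the additive share of the (unit) genetic-plus-
  residual variance equals `h2_true`. Block effects are N(0, block_sd²) in
  an RCBD that spreads each family one-tree-per-block where family size
  permits. For `h2_true = 0` the QTL effects are kept nonzero and the
  residual variance is inflated instead (additive share 1e-4), so the
  degenerate "all effects exactly zero" case never arises.
* **Determinism.** All randomness flows from one `numpy` Generator; the same
  seed reproduces the output bit for bit.

What the generator does **not** emulate: genotyping-chip error and cluster
calling, selection/mortality during the trial (frost culling, thinning),
pedigree errors (mislabeled families, pollen contamination), overlapping
generations, and non-additive genetic variance. Tests passing on this bed
show the estimators are correct under their own assumptions — they do not
certify performance under pedigree misidentification or GxE, which real
trials do exhibit.

## Genotype QC and SNP subsets

Filtering keeps markers with call rate ≥ 0.90 and, at the default
`maf_min = 0`, strictly polymorphic markers (MAF > 0); a positive threshold
is applied inclusively (MAF ≥ 0.05), matching the usual reporting
convention. Mean imputation replaces each missing call by the marker's
observed mean dosage. LD pruning is a greedy within-chromosome pass over
100-kb windows sliding one SNP at a time: any surviving pair with r² > 0.2
loses its lower-MAF member (ties: the later position), computed on
mean-imputed dosages so the result is deterministic; the implementation
guarantees no retained within-window pair exceeds the threshold.

Six subset schemes are provided: a chromosome-stratified *cumulative* random
ladder (each smaller set nested in the next, implemented by interleaving
per-chromosome permutations by fractional rank so any prefix is a
proportional stratified sample), non-cumulative random sets, evenly spaced
SNPs (the SNP closest to the midpoint of each non-overlapping window),
genic/intergenic partitions against a BED annotation, the LD-pruned panel,
and single chromosomes.

## LD statistics, decay and Ne

Pairwise LD is the squared Pearson correlation of dosage vectors within a
chromosome up to 100 kb (configurable). Corrected variants follow the
projection/whitening construction: genotype vectors are whitened by
K^(-1/2) of a kinship matrix (r²V, Powell GRM by convention), residualized
on structure covariates (r²S), or both (r²VS), before squaring the
correlation; with K = I and no covariates all four coincide to 1e-10. The
whitener uses a symmetric eigen square root with eigenvalues floored at
1e-3 of the largest eigenvalue: GRMs from finite panels are near-singular
and the Powell estimator can be slightly indefinite, and an absolute tiny
floor would amplify the clipped directions by orders of magnitude, injecting
noise into the corrected correlations (observed as corrected LD exceeding
raw LD before the relative floor was adopted).

Decay is fitted by least squares of the Hill–Weir drift-sampling
expectation E[r²](C, n) with C = c·d, all pairs weighted equally. The 1-D
problem is solved on a wide log grid with bounded refinement (immune to
bracketing failures on flat tails). The distance where the fitted curve
crosses a level (default r² = 0.2) is solved numerically; it is reported as
infinite when the curve stays above the level, and as 0.0 when the curve is
already below the level at the smallest observed distance (the Hill–Weir
curve has a positive floor ≈ 1/n, so "all r² ≈ 0" data fall in this case).

The effective population size uses the LD (Burrows composite) method on
physically unlinked pairs: inter-chromosomal pairs only, which avoids decay
contamination without needing a distance threshold. After excluding MAF <
0.05, the mean squared dosage correlation r̂² is adjusted by the
random-mating sampling expectation for S ≥ 30 (1/S + 3.19/S²) and
back-transformed by Ne = (1/3 + √(1/9 − 2.76·r²'))/(2 r²'); a non-positive
adjusted r²' is reported as infinite Ne. The parametric CI treats the number
of independent comparisons as chi-square degrees of freedom on the mean r².
In simulation recovery at true Ne = 50 with ~500 OP offspring and 2500
unlinked pairs the median estimate over seeds falls around 44–50 — family
structure in the sample biases the composite r̂² slightly upward (Ne
downward), which is also the regime breeding-population estimates live in.

## Relationship matrices, PCA and splits

The pedigree matrix A is the one-generation OP expectation (diagonal 1,
0.25 between maternal half-sibs, 0 otherwise). The genomic matrix follows
VanRaden's first method, G = WW'/(2Σp(1−p)) with W the dosage matrix
centered by 2p; monomorphic markers drop out of both numerator and scale.
The Powell–Visscher–Balding estimator (per-locus standardized identity,
with the 1+F diagonal) is used for LD corrections. PCA is the eigen
decomposition of G (identical, up to sign, to the SVD of centered-scaled
dosages); k-means (k = 2, seeded restarts) on the leading two PCs defines
the relatedness-minimized split after removing outliers beyond 6 SD on any
leading PC (the outlier rule is a configurable invention — the study design
it emulates removed outliers without stating a rule). The larger cluster
trains, the smaller validates; the random control reproduces the same set
sizes with uniform membership.

## Mixed models and the Bayesian alphabet

The core model is y = Xb + Za + e with fixed block (and optional structure)
effects and a ~ N(0, Kσ²a) for K = A (ABLUP) or K = G (GBLUP). REML uses
the single-random-effect spectral method: one eigen decomposition of K
projected off X turns the restricted likelihood into a cheap function of
the variance ratio, maximized on the log scale over [1e-6, 1e6] (grid +
Brent, 1e-8 tolerance); boundary solutions are flagged rather than raised,
since pedigree h² estimates of zero do occur in real data. h² = σ²a/(σ²a +
σ²e). RR-BLUP marker effects are the ridge solution at the REML variance
components; building G from the same centered markers makes GEBV_Z = Zm̂
reproduce the GBLUP BLUPs to 1e-6 relative — this identity is asserted in
the tests.

The five Bayesian regressions (BRR, Bayes A, Bayes B, Bayes Cπ, Bayesian
Lasso) share the base model y = Xb + Zm + e, b ~ N(0, 10⁶I), σ²e ~
scaled-inv-χ²(ν_e, S_e), and differ in the marker-effect prior: common
normal variance (BRR); per-marker scaled-inv-χ² variances (Bayes A); per-
marker variances with a point mass at zero and a Beta(1,1)-updated
exclusion probability started at 0.99 (Bayes B); common variance with point
mass and Beta-updated π (Bayes Cπ); double-exponential via its exponential
scale mixture with inverse-Gaussian latent updates and a Gamma-updated λ²
(BL). Hyperparameters default to ν_e = ν_m = 5 with scales solved so the
prior mode implies a 50% genomic variance share — the convention of the
standard whole-genome-regression software, and configurable. The samplers
run a single-site Gibbs sweep (numba-compiled) with all random draws taken
from a seeded numpy Generator, so chains are exactly reproducible. The
production schedule is 200k iterations / 50k burn-in / thin 5; tests and
the analysis drivers use shorter chains (documented per call) because the
posterior means of interest stabilize within a few hundred sweeps at these
sample sizes. Posterior h² is summarized as Var(Zm)/(Var(Zm) + σ²e) per
kept sample; note this quantity does not concentrate below ~0.1 under a
null trait for ridge-type priors at small n·p — the spike-and-slab methods
do, and the null-recovery tests use them accordingly.

Cross-validation is a seeded k-fold partition (default 10). Kinship-route
methods refit REML per training fold and project validation GEBVs through
the training-fold covariance; marker-route methods re-estimate effects per
fold and predict validation GEBVs as Z_v·m̂ with training-fold centering.
Fold predictive ability r_gy is the Pearson correlation between validation
phenotypes and GEBVs **after removing the training-estimated block
effects** — whether the original analysis adjusted validation phenotypes is
unstated, so the choice is explicit and toggleable
(`adjust_validation=False` for raw phenotypes). Block levels unobserved in
a training fold are dropped from the design for that fold.

## GWAS

LMA regresses the phenotype on each SNP plus covariates by OLS; MLMA adds a
polygenic effect g ~ N(0, Gσ²g) whose variance components are estimated
once under the null (the population-parameters-previously-determined
approximation, as in the standard implementation) and tests each SNP by
GLS in the whitened space, with the candidate's chromosome left in the GRM
(no leave-one-chromosome-out). The residual scale is re-estimated per SNP
in both scans, so MLMA with G = I reduces to LMA exactly. Monomorphic or
covariate-collinear SNPs are flagged with β = 0, p = 1. Bonferroni (α =
0.05) and Benjamini–Hochberg (FDR = 5%) adjustments follow their literal
definitions; λ_gc = median(χ²)/0.4549. On structured polygenic simulations
LMA inflates (λ ≈ 1.5–3) while MLMA stays within [0.9, 1.1], reproducing
the familiar Q-Q contrast.

## Numerical and engineering choices

* Kinship matrices are symmetrized and, where REML requires positive
  semidefiniteness, repaired with the minimal ridge (|λ_min| + 1e-8)·I.
* The pipeline derives per-stage child seeds from one global seed via
  `SeedSequence.spawn`; reports omit wall-clock time so reruns are
  byte-identical.
* Problem sizes in tests and drivers (e.g. 700-sweep chains for h² recovery,
  8–20 seed replicates, 2500–19.5k markers) were chosen as the smallest
  sizes at which the quantities under test are stable, and are stated at
  each call site.
* PLINK-1 binary IO is a ~60-line codec written here (SNP-major 2-bit
  format); VCF reading uses cyvcf2 when installed, writing is plain-text
  v4.2 with GT only.

## Known limitations

* Single trait, additive-only, single random effect; no GxE, dominance or
  single-step blending.
* The pedigree A matrix covers exactly one generation of maternal half-sib
  families; bulked or mislabeled seed lots are out of scope.
* LDNe assumes random mating and S ≥ 30; the family structure of progeny
  trials biases it mildly downward (documented above), and the
  between-chromosome pair choice is a package decision the original
  LD-based estimators leave implicit.
* The simulated LD decay scale (Mbp at Ne = 35–50 under uniform 1 cM/Mbp)
  is much longer than chip-based decay estimates in real eucalypt stands,
  which reflect large historical recombination; all decay tests therefore
  compare relative, not absolute, distances.
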