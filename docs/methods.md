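# Methods

This package re-implements, as a tested pipeline, the genomic-selection
analysis of a two-site control-pollinated Norway spruce progeny test: a
partial diallel of 55 parents and 128 full-sib families with roughly 1300
trees per site, genotyped at biallelic SNPs and phenotyped for a
low-heritability growth trait (tree height) and moderate-heritability wood
traits (Pilodyn penetration, acoustic velocity, MOE).  Because the trial's
raw data are not distributable, every stage runs against synthetic trials
whose statistical structure matches the design; the generator is therefore
first-class, tested code.

## Synthetic trials

**Pedigree.** Families are distinct unordered parent pairs drawn uniformly
from the 55×54/2 possible crosses; per-family-per-site progeny counts are
uniform on 5–20 (configurable).  Trees are assigned to one of two sites and
to one of 44 post-blocks within site, mirroring the randomized single-tree
plot layout.

**Genotypes.** Founder allele frequencies are uniform on the configured MAF
range, default (0.05, 0.5].  Founders receive two i.i.d. Bernoulli(p)
alleles per locus; each offspring inherits one allele chosen at random from
each parent's pair, independently per locus (gene dropping).  Markers are
unlinked: in this design prediction is dominated by relatedness rather than
population-level marker–QTL LD, and the conclusions the pipeline probes
(relatedness orderings, G×E, marker-subset behaviour) do not hinge on the
within-contig LD of the real assay.  Linked-marker simulation is out of
scope.

**Phenotypes.** For each trait, `n_qtl` markers (a subset of the genotyped
ones — the captured-QTL regime; other markers are neutral) receive per-site
effects from a bivariate normal whose correlation is the trait's type-B
target.  With type-B = 1 the same effect vector is used at both sites
exactly.  Per-site effects are rescaled so the founder-population additive
variance Σ 2p(1−p)β² equals 1; residual variance is then (1−h²)/h², giving
the target narrow-sense h² in expectation.  Post-block effects are i.i.d.
normal with variance equal to 10% of σ²_a+σ²_e (the study reports no block
variance; 10% is a stand-in typical of well-blocked forest trials), and
sites get fixed offsets.  Traits are mapped onto nominal measurement scales
(cm, mm, km/s, GPa).  Trait presets follow the study's Table-1 genetic
architecture: height (h² 0.15, type-B 0.45), Pilodyn (0.40, 0.90), velocity
(0.50, 0.85), MOE (0.45, 0.90).

What the generator does **not** emulate: linkage and LD decay, dominance and
epistasis, spatial autocorrelation beyond blocks, selection over
generations, genotyping error beyond what the QC fixtures inject.  Passing
tests therefore demonstrate correctness of the estimation machinery and the
internal consistency of the study's design conclusions under an additive,
unlinked-marker world — not reproduction of the study's real-data accuracy
values, which depend on its unreleased phenotypes.

## Genotype QC

Filters run in a fixed order: drop indels; keep biallelic records; set
genotypes with GQ < 6 or DP < 2 missing; drop samples with call rate < 50%;
drop variants with call rate < 90% or MAF < 1%.  All inequalities are
strict.  MAF is recomputed after sample removal so frequencies reflect
retained samples.  Imputation is mean (missing ← 2p, real-valued dosages
allowed downstream) or random (HWE draw at p); the original LD-kNN
imputation is out of scope.  Technical-replicate discordance is the mean
over pairs of the fraction of jointly called markers that disagree.

## Relationship matrices

A uses the tabular recursion (founders diagonal 1; A_ii = 1 + 0.5·A_sd).
G is VanRaden's ratio (M−P)(M−P)ᵀ / 2Σp(1−p) on 0/1/2 dosages with minor
orientation.  The study prints P columns as 2(p−0.5), which centers a
−1/0/1 coding rather than 0/1/2; the default here is the standard
`vanraden` centering (P = 2p), with the printed form available as
`paper_literal` for comparison.  Inversion is Cholesky-based with an
automatic, logged 10⁻⁶ ridge fallback for rank-deficient G.

## Mixed models

The joint-site animal model is y = Xβ + W b(s) + Z a + e with fixed grand
mean and site, random post-blocks, additive effects with covariance
Σ ⊗ K (K = A or G; Σ the 2×2 across-site additive covariance), and
heteroscedastic residuals.  Variance components are estimated by
average-information REML: all model families used here have covariance
linear in the parameters, so scores and AI terms come from one engine with
step-halving, an EM fallback (monotone for variance parameters), and an
active set that freezes parameters pinned at the positive floor
(10⁻⁸ × phenotypic variance).  Convergence: |Δlogℓ| < 10⁻⁶ and max relative
parameter change < 10⁻⁴, 200 iterations maximum; a flat likelihood along a
weakly identified direction for three successive iterations also terminates
(flagged converged-at-boundary).  The commercial REML package the study
used is not required anywhere.

EBVs/GEBVs come from û = Cov(u, y) V⁻¹(y − Xβ̂), algebraically identical to
Henderson's mixed-model equations (the MME block system is also implemented
and the equivalence is property-tested).  Per-site EBVs from the joint
unstructured fit are the reference breeding values; their mean serves the
joint scope, matching the study's convention of averaging site breeding
values.  For cross-validation the model on adjusted phenotypes reduces to
one kinship plus residual, fitted on a fast path: one eigendecomposition of
K then Brent profiling of the variance ratio.

Heritability is h² = σ²_a/(σ²_a + σ²_e) — block variance excluded, matching
the printed arithmetic of the study's component table; the site×additive
component of the homogeneous joint model is likewise excluded by default
(the printed joint h² values are consistent with that choice), with a flag
to include it.  SEs come from the delta method on the inverse AI matrix.
Type-B correlation is σ_a12/√(σ²_a1 σ²_a2).  The test of type-B = 1 is a
one-tailed boundary LRT: the constrained fit fixes the correlation at 1
while keeping per-site variances free (profiling the site-2/site-1 scaling,
each inner problem linear), and the statistic is referred to a 50:50
mixture of χ²₀ and χ²₁ — the study does not state its reference
distribution; the mixture is the standard choice for a boundary test, and a
200-replicate simulation at the null confirms the size is conservative.

**Phenotype adjustment.** y′ subtracts block BLUPs and then standardizes to
zero mean and unit variance within each site.  In cross-validation y′ is
built per site from that site's own fit, so no information crosses sites.

## Marker models

All Bayesian machines run on the −1/0/1 indicator coding (dosage − 1);
G-matrix construction centers 0/1/2 dosages at 2p; the conversions are
centralized and tested.

* **BRR**: common marker variance σ²_m with scaled-inverse-χ² priors on
  σ²_m and σ²_e.  Gibbs sweeps update effects one marker at a time from
  exact normal full conditionals with residual updating.
* **BLASSO**: Park–Casella parameterization a_j ~ N(0, τ²_j σ²_e),
  1/τ²_j inverse-Gaussian given the effect, λ² ~ Gamma(r, δ) updated from
  its Gamma full conditional (defaults r = 1, δ = 0.1; λ² > 10¹² aborts
  with a prior diagnostic).  The study writes the marker-variance scale as
  σ²_m; the σ²_e-scaled form is what keeps every full conditional conjugate
  and is what the BGLR software it used actually samples.
* **RKHS**: genetic values with Gaussian-kernel covariance
  K_ij = exp(−h·d_ij), h = 0.25, d the squared Euclidean genotype distance
  **divided by its off-diagonal mean** (default; raw distances over
  realistic marker counts make exp(−0.25·d) underflow to zero, so h = 0.25
  is only meaningful on a normalized scale — the literal unscaled form is
  available by flag).  The kernel is eigendecomposed once and the model
  fitted in its eigenbasis with the BRR kernel, which also yields
  predictions for unphenotyped individuals through their kernel rows.

Priors default to df = 5 with scales set so the prior mode equals half the
phenotypic variance for the relevant component ("flat priors" is all the
study states).  MCMC presets: `paper` = 150 000 iterations, 50 000 burn-in,
thinning 1000 (100 retained); `desk` = 15 000 / 5 000 / 10 (1000 retained,
tighter Monte Carlo error at desk scale).  Samplers are numba-compiled and
bit-reproducible given the seed.  Convergence diagnostics are Geweke-style
early-vs-late z-scores (|z| > 3 flagged; segment variances treat retained
samples as independent, appropriate after thinning) plus trace plots.

## Cross-validation engine

Scenario cells declare model × site scope × split rule × marker subset ×
replicates.  Splits:

* k-fold (default 10) — every id validates exactly once;
* TS/VS ratios 1:1…9:1 — training size = round(n·r/(r+1)), ties up;
* relatedness — *full-sib*: ~10% of each family validates (families span
  both sets); *half-sib*: whole families validate, with the shared parent
  acting as the dam (present in training through other families) and the
  other parent, acting as the sire, withheld from training entirely — in a
  diallel every parent is both dam and sire, and without withholding the
  sire a validation family's second parent still reaches training through
  its other crosses, which silently restores full-parental TS–VS ties and
  erases the half-sib accuracy drop; *unrelated*: parents partitioned into
  disjoint groups, straddling families discarded, with the partition
  re-sampled up to 50 times if a side is empty;
* family-number and trees-per-family subsampling per the study's designs.

Marker selection (random or largest positive single-marker effect) uses
training data only.  Cross-site scopes train on one entire site and
validate on the other.  Replicate seeds are seed + replicate index and are
recorded in every record.  Accuracy is the Pearson correlation of validation
GEBVs with reference EBVs; predictive ability correlates with y′; both are
flagged undefined (not zero) when a vector is constant — which is exactly
what happens to pedigree BLUPs under the unrelated split, reproducing the
study's footnote that those accuracies are zero.  RE is computed from cell
means, RE/year multiplies by the cycle-length ratio (25 / 12.5 years by
default).

## Problem sizes

Tests and the acceptance script size their simulations so the whole suite
runs comfortably on one CPU: parameter-recovery checks use the full study
design (55 parents / 128 families / ~1300 trees per site, 500 markers with
300 QTL) with 30 replicates in the test suite and 10 in the acceptance
script; structural CV checks use a 30-parent / 60-family / ~1600-marker
polygenic trial; Gibbs samplers run the `desk` preset.  Marker counts far
below the study's 116 765 are adequate because all checks concern
relationship-driven prediction, which saturates once markers estimate
kinship well.

## Known limitations

* Real-data accuracy values from the study are not reproducible (data not
  released); only their internal arithmetic and the structural orderings
  are checked.
* The generator's unlinked markers cannot exhibit the LD-dependent
  marker-subset plateaus of the real assay; the largest-positive-effect
  subset experiment is checked directionally only.
* The LRT reference mixture ignores the extra variance-heterogeneity
  parameter of the unstructured model; the simulated size is conservative
  (below nominal), not exact.
* Type-B estimates for low-heritability traits are widely dispersed at the
  study design (single-replicate SD ≈ 0.25, occasionally negative) and
  mildly attenuated toward zero; replicate means recover the simulated
  value to within about 0.05.
* Mean-imputed dosages are real-valued; integer-only consumers should use
  random imputation.
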