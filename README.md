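# sprucegs

Genomic selection (GS) analysis for two-site conifer progeny trials,
modelled on a Norway spruce (*Picea abies*) breeding study: 1370
control-pollinated progeny from 128 full-sib families (a partial diallel of
55 parents) tested at two sites in northern Sweden, phenotyped for tree
height and wood quality traits (Pilodyn penetration, acoustic velocity,
MOE) and genotyped at exome-capture SNPs.

The package is for tree breeders and quantitative geneticists who want to
ask, on a design like this one: how accurate is marker-based selection
relative to pedigree-based selection, and how do the prediction method,
genotype-by-environment interaction, relatedness between training and
validation sets, and the number of markers, families and trees per family
change that answer?  Because the study's raw data are not released, a
synthetic-trial generator with the same statistical structure drives every
stage, so the full pipeline runs — and is tested — end to end.

## What it implements

* **`simdata`** — partial-diallel pedigrees, gene-dropped SNP genotypes,
  and per-site phenotypes with target narrow-sense heritability h² and
  type-B genetic correlation (the across-site additive correlation
  r_B = σ_a12/√(σ²_a1·σ²_a2); r_B ≪ 1 means strong G×E).  VCF/CSV I/O.
* **`geno_qc`** — the study's seven-step VCF filter (indels, biallelic,
  GQ < 6, DP < 2, individual call rate < 50%, variant call rate < 90%,
  MAF < 1%), replicate discordance, mean/random imputation.
* **`relationship`** — pedigree A matrix (tabular method) and VanRaden
  genomic G = (M−P)(M−P)ᵀ/2Σp(1−p); Cholesky inversion with ridge
  fallback.
* **`lmm`** — AI-REML for the joint-site animal model
  y = Xβ + Wb(s) + Za + e with unstructured across-site additive
  covariance; Henderson mixed-model equations; h², type-B and its
  one-tailed boundary LRT; phenotype adjustment y′.
* **`marker_models`** — Gibbs samplers for Bayesian ridge regression (BRR),
  Bayesian LASSO, and Gaussian-kernel RKHS regression (K = exp(−h·d),
  h = 0.25), with GEBV assembly ĝ_i = Σ_j z_ij â_j.
* **`cv_engine` / `metrics`** — every cross-validation experiment of the
  study (TS/VS ratios, k-fold, family and trees-per-family subsampling,
  full-sib/half-sib/unrelated structures, cross-site and joint-site
  scenarios, random vs largest-positive-effect marker subsets), scored by
  accuracy r(GEBV, EBV), predictive ability r(GEBV, y′), relative
  efficiency RE and RE/year.
* **`pipeline` + CLI** — end-to-end orchestration with a provenance
  manifest: `sprucegs run --config configs/demo.yaml`.

The numbered scripts under `analysis/` walk through the study's analyses on
a desk-scale synthetic trial: simulate → QC → relationship matrices →
variance components → CV grids → report.

## Worked example

```python
from sprucegs.simdata import SimConfig, simulate_trial
from sprucegs.relationship import a_matrix, g_matrix
from sprucegs.lmm import ModelSpec, fit_reml, heritability, type_b_correlation

cfg = SimConfig(
    n_markers=1000, n_qtl=300, n_parents=30, n_families=60,
    progeny_range=(5, 8),
    trait_specs=(("height", 0.15, 0.45), ("pilodyn", 0.40, 0.90)),
    seed=7,
)
ped, geno, pheno, truth = simulate_trial(cfg)
A = a_matrix(ped)
fit = fit_reml(pheno, A, ModelSpec(trait="pilodyn", kinship="A", scope="joint"))
h2, se = heritability(fit.vc, site="site1")
print(f"h2(site1) = {h2:.2f} ({se:.2f}),  type-B = {type_b_correlation(fit.vc):.2f}")
```

prints

```
h2(site1) = 0.23 (0.10),  type-B = 0.80
```

a pedigree-model estimate of the site-1 narrow-sense heritability (true
simulated value 0.40) with its delta-method standard error, and the type-B
genetic correlation between the two sites (true value 0.90): a
moderate-heritability wood trait with weak G×E, like the study's Pilodyn
trait.  A single ~450-tree realization estimates both parameters with
considerable noise — the test suite checks recovery as means over 30
replicates at the study's full design.  Fitting the same model with
`g_matrix(...)` instead of A gives the GBLUP estimates.

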