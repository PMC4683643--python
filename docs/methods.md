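# Methods

## The model

`clonalgp` analyses clonally replicated, SNP-genotyped trial populations in
two stages.

**Stage 1 — adjusted phenotypes.** Within each site, records per clonal
replicate × year are collapsed to one value per individual by ordinary least
squares with genotype, year and replicate all fixed
(`value ~ genotype + year + replicate`). The genotype estimate is a BLUE
(unshrunk), re-centred so its mean equals the site trait mean. Year and
replicate enter as additive main effects; the model statement behind the
source analysis does not specify an interaction, and with ≤ 4 replicates ×
2 years there is little information to support one. BLUE precision is not
propagated to stage 2 — each individual-site cell contributes one equally
weighted record, so heterogeneous replication (1–4 clones) surfaces only
through residual noise. This is a known simplification.

**Stage 2 — multi-kernel GBLUP.** Stacking the per-site BLUEs site-major
into y (ns × 1),

    y = Xb + Z1 a + Z2 d + Z3 i + Z4 t1 + Z5 t2 + Z6 t3 + e

with fixed effects b = (intercept, site); a ~ N(0, G_a σ²a),
d ~ N(0, G_d σ²d), i ~ N(0, G_aa σ²aa) the main additive, dominance and
additive×additive epistatic effects; t1–t3 ~ N(0, I_s ⊗ G σ²_g×s) their
site interactions; and e ~ N(0, I σ²e). Model variants A, AD and ADE keep
the first one, two or all three genetic kernels (with their interactions).
Under site-major ordering each main kernel contributes 1_s1_s' ⊗ G to
Var(y) and each interaction I_s ⊗ G; individuals missing at a site are
handled by dropping rows, which subsets every structure consistently.

Kernels follow the classical genomic-relationship constructions: dosages
centred at 2p give G_a = MM'/Σ2p_jq_j; heterozygosity indicators centred at
2pq give G_d = HH'/Σ2p_jq_j(1−2p_jq_j); G_aa is the Hadamard square of G_a
(PSD by the Schur product theorem). Allele frequencies are the observed
sample frequencies — base-population frequencies are generally unavailable
for such trials. All three constructions are invariant to which allele is
counted at any SNP (tested). Pedigree A (tabular method) and D
(non-inbred product formula) are provided for comparison. Kernels are
conditioned by minimal diagonal inflation (|λ_min| + ε added when λ_min < 0,
flagged) because REML needs an invertible V; bending is standard and
minimally invasive.

Note that sample-frequency centring makes the raw G_a off-diagonals average
≈ 0 by construction (column sums of M are zero), so G_a entries are
comparable to pedigree relationships only after location/scale calibration;
variance components are unaffected because they are reported as fractions
of their sum, which absorbs kernel scale.

## REML

Variance components maximize the restricted log-likelihood
−½[log|V| + log|X'V⁻¹X| + y'Py]. Iterations take an average-information
(AI) step in log-variance space — which keeps every component positive and
drives boundary components to the floor geometrically — with
Levenberg–Marquardt damping escalated whenever the AI direction fails, and
an expectation–maximization step (guaranteed ascent) as the final fallback.
A proposal is accepted only if it does not decrease the restricted
log-likelihood, so the likelihood trace is non-decreasing. Components are
floored at 1e−8 × var(y) and flagged as boundary estimates, mirroring the
"0.00" rows that constrained REML packages print. Starting values split the
phenotypic variance equally across active components; convergence requires
|Δ log-likelihood| < 1e−6 and relative component change < 1e−4, within 200
iterations (a fit that runs out is returned flagged, not raised). Fits at
trial scale (n ≈ 250, two sites, seven components) converge in ~10–40
iterations.

Derived quantities: h² = σ²a/σ²_total, H² = (σ²a+σ²d+σ²aa)/σ²_total with
the total being the sum of every component in the fitted model; the
between-site genotypic correlation is the ratio
r_B = σ²_G/(σ²_G + σ²_G×S) of main genetic variance to main-plus-interaction
variance — the classical ratio relating genetic covariance across sites to
within-site genetic variance. The exact published formula is not printed in
the source; this inferred form reproduces all six published r_B values from
the published component tables, which is the validation we rely on.

Model comparison uses the likelihood-ratio test with the plain chi-square
reference and df = the difference in the number of variance components
(4 for ADE vs A with interactions), matching the source analysis. Because
the tested components sit on the boundary under the null, the plain
reference is conservative; a chi-bar-square mixture p-value (binomial
weights over χ²_0..χ²_df) is reported alongside as a diagnostic, never
silently substituted.

BLUPs of all random effects use the V-inverse projection û = σ²·Cov(u,y)·Py.
Genetic values for individuals without records come through the kernel
cross-covariance — the prediction path used in cross-validation. The
additive-only special case is algebraically identical to ridge-regression
BLUP on centred marker codings with λ = σ²e/(σ²a/Σ2pq); a test verifies
this against an independent marker-equation solve to 1e−6.

## Cross-validation

Leave-one-family-out: each full-sib family in turn is the validation
population. Variance components are re-estimated within every training fold
(the source is silent on this; re-estimating prevents leakage). Two
strategies: the validation family removed at both sites, or at one target
site only. Accuracy is the correlation of predicted genetic values
(GEGV = a+d+i / a+d / a per variant) with the all-data ADE BLUP-GV — a
single reference for all variants, so A and ADE accuracies are comparable;
bias is the slope of BLUP-GV on GEGV. Unweighted family means are reported.

One caveat the test suite makes explicit: because the BLUP-GV reference is
itself a model output, it shares shrinkage structure with the predictions.
For traits with (near-)zero heritability this inflates apparent accuracy —
both reference and prediction lean on the same relatives' phenotypes. The
no-signal and heritability-monotonicity tests therefore score predictions
against the simulated truth or the held-out family's observed BLUEs, where
the expected behaviour (accuracy ≈ 0 without signal, increasing with h²) is
well defined.

## The synthetic trial generator

The generator emulates the design the analysis assumes: interrelated
parents, full-sib families, biallelic SNPs, two sites, clonal replicates
and years. Defaults are the trial conditions the package is built around —
25 parents, 17 families × 15 offspring, 2828 SNPs with MAF ≥ 0.05, 2 sites
× 4 replicates × 2 years, and per-trait variance profiles spanning
additive-dominated to epistasis-heavy architectures.

* Founders: per-locus allele frequencies uniform on [0.05, 0.95];
  grandparents drawn at Hardy–Weinberg proportions and parents gene-dropped
  from random grandparent pairs. A pool of 7 grandparents gives a mean
  pedigree relationship among parents of ≈ 1/7 ≈ 0.15, the background
  relatedness level of the emulated trial.
* Gene drop: fair Mendelian sampling at unlinked loci. Linkage and LD are
  deliberately not modelled — the variance model only needs the covariance
  structure, and unlinked loci keep realized kernels well conditioned.
* Pedigree errors: with probability `contamination_rate` an offspring's
  transmitting sire is replaced by a random other parent while the recorded
  pedigree is left unchanged, emulating pollen contamination/mislabeling.
* Effects: additive = per-locus normal effects on centred dosages;
  dominance = normal effects on centred heterozygosity codings; epistasis =
  normal effects on pairwise products of centred additive codings over
  2 × n_snps random locus pairs (variance a G_aa-type kernel can capture,
  making recovery tests meaningful). Site deviations are drawn per site
  with covariance proportional to the corresponding realized kernel.
* Every component is rescaled **exactly** on its realized variance, removing
  one source of Monte-Carlo noise from recovery tests. The residual target
  is defined at the individual × site level — the level the stage-2
  decomposition sees — so record-level noise is rescaled on its
  per-(individual, site) means; otherwise replicate × year averaging would
  shrink the realized residual fraction ~8-fold relative to the target.
* Year/replicate/site fixed effects are equally spaced constants (defaults
  0.25/0.10/0.25 × trait SD). Their magnitudes are nuisance — the emulated
  trial reports none — and exist so that stage 1 has something to remove.

What the generator does not emulate: linkage disequilibrium (a recognized
driver of additive/nonadditive confounding in the real data), selection,
higher-order epistasis, multi-trait correlations, spatial field trends, and
unbalanced replication. Passing recovery tests therefore demonstrate that
the estimator recovers architectures matching its own covariance
assumptions at trial scale — not that the real data's LD-driven effects are
resolved.

## What recovery tests can and cannot show

At trial scale (n ≈ 250) the seven kernels are substantially collinear:
G_aa correlates strongly with G_a in family-structured populations, and the
interaction structures I_s ⊗ G_aa are close to the residual identity for
weakly related pairs. Constrained REML then shows visible finite-sample
behaviour: components whose truth is zero are estimated ≥ 0 (boundary
bias), compensated by neighbouring components. Aggregates are robust —
total genetic variance, h², H², r_B and the interaction sum recover well —
but the split between individual collinear components can sit outside tight
unbiasedness bands for particular architectures. The acceptance suite
checks the strict component-wise criterion and reports per-component
diagnostics when it is exceeded.

## Numerical and edge-case decisions

* Missing genotypes: mean imputation (2p per SNP), deterministic and
  sufficient for kernel construction; phasing-based imputation is out of
  scope. A SNP with no observed calls is an error.
* Marker QC order: missingness filter, then MAF; idempotent.
* Genotypes dropped when an individual has no phenotype records (logged).
* Degenerate designs: a year or replicate level observed on fewer than two
  genotypes is rejected by name; duplicate phenotype records and cyclic
  pedigrees are errors.
* LRT of non-nested variants is an error; identical log-likelihoods give
  statistic 0, p = 1.
* Accuracy is undefined (NaN) when predictions or reference are constant;
  CV folds with fewer than three validation members are skipped with a
  warning.
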