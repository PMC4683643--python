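# clonalgp

Genome-enabled decomposition of quantitative phenotypes from clonally
replicated trials into **additive, dominance and additive×additive epistatic
variance**, with genotype-by-site interaction, plus **family-wise
cross-validation** of genomic prediction accuracy and bias.

The package is aimed at breeders and quantitative geneticists running
clonal progeny trials (fruit trees, forest trees, other asexually
propagated crops) where both the breeding value (what transmits to
offspring) and the total genetic value (what a clone itself will do) matter.

## The model

The analysis is two-step. Stage 1 collapses clonal-replicate × year records
to one adjusted phenotype (BLUE) per individual per site. Stage 2 fits the
multi-kernel GBLUP mixed model to the stacked per-site BLUEs **y** (ns × 1):

    y = Xb + Z1 a + Z2 d + Z3 i + Z4 t1 + Z5 t2 + Z6 t3 + e

with a ~ N(0, G_a σ²a), d ~ N(0, G_d σ²d), i ~ N(0, G_aa σ²aa), site
interactions t1–t3 ~ N(0, I_s ⊗ G σ²_g×s), and e ~ N(0, I σ²e). The kernels
are the classical genomic relationship matrices: G_a = MM′/Σ2p_jq_j with
dosages centred at 2p, G_d = HH′/Σ2p_jq_j(1−2p_jq_j) with centred
heterozygosity codings, and G_aa = G_a # G_a (Hadamard product). Variance
components are estimated by AI-REML (log-scale average-information steps
with EM fallback). Derived summaries: narrow- and broad-sense heritability
h² = σ²a/σ²_total and H² = (σ²a+σ²d+σ²aa)/σ²_total, and the between-site
genotypic correlation r_B = σ²_G/(σ²_G + σ²_G×S). Model variants A, AD and
ADE nest and are compared by likelihood-ratio test.

Cross-validation leaves each full-sib family out in turn, either unobserved
at both sites or observed at one site only, and scores predicted genetic
values (GEGV) against the all-data BLUP-GV reference.

A synthetic clonal-trial generator (`clonalgp.simulate`) with known ground
truth drives the parameter-recovery and invariance tests; its defaults
emulate a two-site apple trial of 17 full-sib families from 25 interrelated
parents genotyped at ~2.8k SNPs.

## Worked example

```python
import clonalgp as cg

# a trial-scale synthetic dataset with an additive-dominated architecture
cfg = cg.SimConfig(seed=7)                      # 17 families x 15 offspring, 2828 SNPs
ds  = cg.simulate_dataset(cfg)

blues   = cg.compute_blues_all(ds.phenotypes)   # stage 1: one BLUE per individual-site
kernels = cg.build_kernel_set(ds.offspring)     # G_a, G_d, G_aa

model = cg.KernelGBLUP(kernels=kernels, variant="ADE")
model.fit(blues[["individual_id", "site"]], blues["blue_value"].to_numpy())

print("converged", model.converged_, "iterations", model.n_iter_)
print("fractions", {k: round(100 * v, 2) for k, v in model.fractions_.items()})
print("h2", round(model.h2_, 2), "H2", round(model.H2_, 2), "rB", round(model.rB_, 2))
```

prints

```
converged True iterations 18
fractions {'a': 48.06, 'd': 0.0, 'aa': 30.21, 'a_site': 6.09, 'd_site': 0.0, 'aa_site': 1.54, 'e': 14.1}
h2 0.48 H2 0.78 rB 0.91
```

Read: the fitted ADE model attributes ~48% of phenotypic variance to
additive effects and ~30% to additive×additive epistasis for this
realization (the generating truth was 51.8/6.7/18.4 — at n ≈ 250 the three
genetic kernels are collinear and single-fit splits are noisy, which is
exactly what the package's recovery tests quantify); h² is the additive
fraction, H² the total-genetic fraction, and r_B ≈ 0.91 says genetic
rankings are highly consistent across the two sites. `model.gegv_` holds
the predicted genetic value per individual; `cg.cv_untested(...)` /
`cg.cv_single_site(...)` run the family-wise cross-validation.

A command line mirrors the pipeline: `clonalgp simulate`, `clonalgp qc`,
`clonalgp run`, `clonalgp cv` (see `--help`).

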