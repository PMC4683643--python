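"""Synthetic clonal-trial generator with known genetic ground truth.

Emulates the structure the analysis assumes: a set of interrelated parents
(their background relatedness induced by descent from a small grandparental
pool), full-sib families produced by gene-dropping unlinked biallelic SNPs,
and phenotype records per clonal replicate × site × year generated from
per-locus additive and dominance effects, pairwise additive×additive
epistasis, genetic-by-site deviations and residual noise.

Every variance component is rescaled exactly on its realized (not expected)
variance, so the generated data hit the configured variance fractions up to
the orthogonality of the component vectors — which makes parameter-recovery
tests sharp. Loci are unlinked; linkage disequilibrium is deliberately not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import COMPONENT_KEYS, GenotypeMatrix, PedigreeTable
from .kernels import build_Ga, build_Gaa, build_Gd, condition_kernel

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedDataset",
    "simulate_founders",
    "gene_drop",
    "simulate_phenotypes",
    "simulate_dataset",
    "TRAIT_PROFILES",
]

#: trait architectures spanning the observed variance profiles, as fractions
#: of phenotypic variance (additive, dominance, epistasis, their site
#: interactions, residual). WT is additive-dominated; FIN epistasis-heavy.
TRAIT_PROFILES: dict[str, dict[str, float]] = {
    "WT": {"a": 0.5179, "d": 0.0670, "aa": 0.1838, "a_site": 0.0231, "d_site": 0.0202, "aa_site": 0.0000, "e": 0.1880},
    "GRE": {"a": 0.2652, "d": 0.2286, "aa": 0.2364, "a_site": 0.0108, "d_site": 0.0172, "aa_site": 0.0801, "e": 0.1617},
    "FF": {"a": 0.4963, "d": 0.1999, "aa": 0.0915, "a_site": 0.0132, "d_site": 0.0436, "aa_site": 0.0000, "e": 0.1556},
    "CRI": {"a": 0.2339, "d": 0.2337, "aa": 0.1917, "a_site": 0.0338, "d_site": 0.0000, "aa_site": 0.0000, "e": 0.3070},
    "JUI": {"a": 0.1805, "d": 0.2378, "aa": 0.1858, "a_site": 0.0000, "d_site": 0.0000, "aa_site": 0.0457, "e": 0.3502},
    "FIN": {"a": 0.1067, "d": 0.0000, "aa": 0.2341, "a_site": 0.0080, "d_site": 0.0095, "aa_site": 0.0302, "e": 0.6116},
}


@dataclass
class SimConfig:
    """Scenario configuration for the synthetic clonal trial.

    Defaults emulate the study conditions the package is built around:
    25 interrelated parents, 17 full-sib families of 15 offspring, ~2828
    post-QC SNPs with MAF >= 0.05, 2 sites × 4 clonal replicates × 2 years,
    and an additive-dominated trait architecture. ``n_grandparents`` sets the
    founder-pool depth; a pool of 7 gives parents a mean pedigree
    relationship near 0.15. Year/replicate/site effects are fixed, equally
    spaced constants (their magnitudes are nuisance — stage 1 only needs
    something to remove).
    """

    n_parents: int = 25
    n_families: int = 17
    family_size: int = 15
    n_snps: int = 2828
    maf_floor: float = 0.05
    fixed_maf: float | None = None
    n_sites: int = 2
    n_reps: int = 4
    n_years: int = 2
    var_components: dict[str, float] = field(
        default_factory=lambda: dict(TRAIT_PROFILES["WT"])
    )
    contamination_rate: float = 0.0
    seed: int = 0
    n_grandparents: int = 7
    trait_name: str = "trait"
    trait_mean: float = 0.0
    trait_sd: float = 1.0
    year_effect_spacing: float = 0.25
    rep_effect_spacing: float = 0.10
    site_effect_spacing: float = 0.25
    epistatic_pairs_factor: int = 2

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_parents < 2:
            raise ValueError("need n_snps >= 1 and n_parents >= 2")
        if min(self.n_families, self.family_size, self.n_sites, self.n_reps, self.n_years) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError("contamination_rate must be a probability")
        unknown = set(self.var_components) - set(COMPONENT_KEYS)
        if unknown:
            raise ValueError(f"unknown variance components: {sorted(unknown)}")
        total = sum(self.var_components.values())
        # printed-percentage profiles can be off by rounding; renormalize
        if abs(total - 1.0) > 5e-3:
            raise ValueError(f"variance fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.var_components.values()):
            raise ValueError("variance fractions must be nonnegative")
        self.var_components = {k: v / total for k, v in self.var_components.items()}
        max_pairs = self.n_parents * (self.n_parents - 1) // 2
        if self.n_families > max_pairs:
            raise ValueError("more families than available parent pairs")

    def target(self, key: str) -> float:
        return float(self.var_components.get(key, 0.0))


@dataclass
class SimTruth:
    """Ground-truth genetic effects behind a simulated phenotype set."""

    true_a: np.ndarray
    true_d: np.ndarray
    true_i: np.ndarray
    true_site_deviations: dict[str, np.ndarray]  # component -> (n, n_sites)
    realized_fractions: dict[str, float]
    individual_ids: list[str]


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces."""

    config: SimConfig
    parents: GenotypeMatrix
    offspring: GenotypeMatrix
    pedigree: PedigreeTable  # recorded pedigree (grandparents -> offspring)
    families: dict[str, str]  # offspring id -> family label
    actual_sires: dict[str, str]  # truth, differs from record under contamination
    phenotypes: pd.DataFrame
    truth: SimTruth


def _gametes(dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One fair-Mendelian gamete per individual per (unlinked) locus."""
    het = dosages == 1.0
    out = (dosages == 2.0).astype(float)
    out[het] = rng.integers(0, 2, size=int(het.sum())).astype(float)
    return out


def simulate_founders(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, PedigreeTable]:
    """Simulate the parental generation and its recorded pedigree.

    Per-locus allele frequencies are drawn uniformly on
    [maf_floor, 1 - maf_floor] (or fixed at ``fixed_maf``); grandparents are
    sampled at Hardy–Weinberg proportions and each parent is gene-dropped
    from a random grandparent pair, which induces background relatedness
    among parents of about 1/n_grandparents. With ``n_grandparents = 0`` the
    parents themselves are unrelated HWE draws.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m = config.n_snps
    if config.fixed_maf is not None:
        p = np.full(m, config.fixed_maf)
    else:
        p = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=m)

    parent_ids = [f"P{i+1:03d}" for i in range(config.n_parents)]
    if config.n_grandparents <= 0:
        dosages = rng.binomial(2, p, size=(config.n_parents, m)).astype(float)
        ped = PedigreeTable(parent_ids, [None] * len(parent_ids), [None] * len(parent_ids))
        return GenotypeMatrix(parent_ids, _snp_ids(m), dosages), ped

    gp_ids = [f"G{i+1:03d}" for i in range(config.n_grandparents)]
    gp = rng.binomial(2, p, size=(config.n_grandparents, m)).astype(float)
    sires, dams, dosages = [], [], np.empty((config.n_parents, m))
    for i in range(config.n_parents):
        gs, gd = rng.choice(config.n_grandparents, size=2, replace=False)
        dosages[i] = _gametes(gp[gs][None, :], rng)[0] + _gametes(gp[gd][None, :], rng)[0]
        sires.append(gp_ids[gs])
        dams.append(gp_ids[gd])
    ped = PedigreeTable(
        gp_ids + parent_ids,
        [None] * len(gp_ids) + sires,
        [None] * len(gp_ids) + dams,
    )
    return GenotypeMatrix(parent_ids, _snp_ids(m), dosages), ped


def _snp_ids(m: int) -> list[str]:
    return [f"snp{j+1:05d}" for j in range(m)]


def gene_drop(
    parents: GenotypeMatrix,
    pedigree: PedigreeTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Drop parental genomes through recorded full-sib matings.

    Each offspring in ``pedigree`` (rows whose sire and dam are both known
    and present in ``parents``) receives one fair-Mendelian gamete per locus
    per parent. With probability ``contamination_rate`` the *transmitting*
    sire is replaced by a random other parent while the recorded pedigree is
    left untouched; the realized sires are returned alongside the genotypes.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    index = {v: i for i, v in enumerate(parents.individual_ids)}
    off_ids, off_sires, off_dams = [], [], []
    for ind, s, d in zip(pedigree.individual_ids, pedigree.sires, pedigree.dams):
        if ind in index:
            continue
        if s is None and d is None:
            continue  # founder of the pedigree, not an offspring to drop
        if s not in index or d not in index:
            raise KeyError(f"unknown parent for {ind!r}: {s!r} x {d!r}")
        off_ids.append(ind)
        off_sires.append(s)
        off_dams.append(d)

    n = len(off_ids)
    dosages = np.empty((n, parents.n_snps))
    actual: dict[str, str] = {}
    for k in range(n):
        sire = off_sires[k]
        if config.contamination_rate > 0 and rng.random() < config.contamination_rate:
            others = [p for p in parents.individual_ids if p != sire]
            sire = others[rng.integers(len(others))]
        actual[off_ids[k]] = sire
        g_s = _gametes(parents.dosages[index[sire]][None, :], rng)[0]
        g_d = _gametes(parents.dosages[index[off_dams[k]]][None, :], rng)[0]
        dosages[k] = g_s + g_d
    return GenotypeMatrix(off_ids, list(parents.snp_ids), dosages), actual


def _rescale(x: np.ndarray, target_var: float) -> np.ndarray:
    """Scale a draw so its realized variance is exactly the target."""
    if target_var <= 0:
        return np.zeros_like(x)
    v = float(np.var(x, ddof=1))
    if v <= 0:
        raise ValueError("degenerate draw cannot be rescaled to positive variance")
    return x * np.sqrt(target_var / v)


def simulate_phenotypes(
    geno: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate phenotype records and ground truth from genotypes.

    Additive effects are per-locus normal draws applied to centred dosages;
    dominance effects apply to centred heterozygosity codings; epistatic
    effects are pairwise products of centred additive codings over
    ``epistatic_pairs_factor × n_snps`` random locus pairs. Genetic-by-site
    deviations are drawn per site with covariance proportional to the
    corresponding realized genomic kernel. Each component is rescaled exactly
    to its target fraction of ``trait_sd**2``; the residual target applies at
    the individual × site level (the level the variance decomposition sees),
    so record-level noise is rescaled on its per-(individual, site) means.

    One record is produced per individual × site × year × clonal replicate.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, m = geno.n_individuals, geno.n_snps
    total = config.trait_sd**2
    p = geno.compute_allele_freqs()
    Mc = geno.dosages - 2.0 * p
    twopq = 2.0 * p * (1.0 - p)
    Hc = np.where(np.isclose(geno.dosages, 1.0), 1.0, 0.0) - twopq

    a = _rescale(Mc @ rng.standard_normal(m), config.target("a") * total)
    d = _rescale(Hc @ rng.standard_normal(m), config.target("d") * total)

    n_pairs = config.epistatic_pairs_factor * m
    jj = rng.integers(0, m, size=n_pairs)
    kk = rng.integers(0, m, size=n_pairs)
    keep = jj != kk
    jj, kk = jj[keep], kk[keep]
    W = Mc[:, jj] * Mc[:, kk]
    epi = _rescale(W @ rng.standard_normal(len(jj)), config.target("aa") * total)

    # genetic-by-site deviations: covariance proportional to the realized kernel
    Ga = condition_kernel(build_Ga(geno)).values
    Gd_ = condition_kernel(build_Gd(geno)).values
    Gaa = condition_kernel(build_Gaa(build_Ga(geno))).values
    site_dev: dict[str, np.ndarray] = {}
    for key, K in (("a_site", Ga), ("d_site", Gd_), ("aa_site", Gaa)):
        tgt = config.target(key) * total
        if tgt <= 0 or config.n_sites < 2:
            site_dev[key] = np.zeros((n, config.n_sites))
            continue
        L = np.linalg.cholesky(K + 1e-8 * np.trace(K) / n * np.eye(n))
        T = np.column_stack([L @ rng.standard_normal(n) for _ in range(config.n_sites)])
        site_dev[key] = _rescale(T, tgt)

    # record-level residual, rescaled on its (individual, site) means
    e_rec = rng.standard_normal((n, config.n_sites, config.n_years, config.n_reps))
    tgt_e = config.target("e") * total
    if tgt_e > 0:
        cell_means = e_rec.mean(axis=(2, 3))
        v = float(np.var(cell_means, ddof=1))
        e_rec = e_rec * np.sqrt(tgt_e / v)
    else:
        e_rec = np.zeros_like(e_rec)

    def spaced(k: int, spacing: float) -> np.ndarray:
        return (np.arange(k) - (k - 1) / 2.0) * spacing * config.trait_sd

    site_eff = spaced(config.n_sites, config.site_effect_spacing)
    year_eff = spaced(config.n_years, config.year_effect_spacing)
    rep_eff = spaced(config.n_reps, config.rep_effect_spacing)

    g_total = a + d + epi
    sites = [f"S{s+1}" for s in range(config.n_sites)]
    years = [2013 + t for t in range(config.n_years)]
    dev_total = site_dev["a_site"] + site_dev["d_site"] + site_dev["aa_site"]

    values = (
        config.trait_mean
        + g_total[:, None, None, None]
        + dev_total[:, :, None, None]
        + site_eff[None, :, None, None]
        + year_eff[None, None, :, None]
        + rep_eff[None, None, None, :]
        + e_rec
    )
    idx = pd.MultiIndex.from_product(
        [geno.individual_ids, sites, years, range(1, config.n_reps + 1)],
        names=["individual_id", "site", "year", "replicate"],
    )
    pheno = idx.to_frame(index=False)
    pheno["trait"] = config.trait_name
    pheno["value"] = values.reshape(-1)

    realized = {
        "a": float(np.var(a, ddof=1)) / total,
        "d": float(np.var(d, ddof=1)) / total,
        "aa": float(np.var(epi, ddof=1)) / total,
        "a_site": float(np.var(site_dev["a_site"], ddof=1)) / total,
        "d_site": float(np.var(site_dev["d_site"], ddof=1)) / total,
        "aa_site": float(np.var(site_dev["aa_site"], ddof=1)) / total,
        "e": float(np.var(e_rec.mean(axis=(2, 3)), ddof=1)) / total,
    }
    truth = SimTruth(a, d, epi, site_dev, realized, list(geno.individual_ids))
    return pheno, truth


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: founders, families, genotypes, phenotypes.

    A single seeded generator drives every draw, so identical configs give
    bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    parents, founder_ped = simulate_founders(config, rng)

    # pick distinct parent pairs as families
    pairs: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    while len(pairs) < config.n_families:
        i, j = rng.choice(config.n_parents, size=2, replace=False)
        key = (min(i, j), max(i, j))
        if key not in seen:
            seen.add(key)
            pairs.append(key)

    off_ids, off_sires, off_dams = [], [], []
    families: dict[str, str] = {}
    for f, (i, j) in enumerate(pairs):
        fam = f"F{f+1:02d}"
        for k in range(config.family_size):
            oid = f"{fam}_{k+1:02d}"
            off_ids.append(oid)
            off_sires.append(parents.individual_ids[i])
            off_dams.append(parents.individual_ids[j])
            families[oid] = fam

    pedigree = PedigreeTable(
        founder_ped.individual_ids + off_ids,
        founder_ped.sires + off_sires,
        founder_ped.dams + off_dams,
    )
    offspring, actual_sires = gene_drop(parents, pedigree, config, rng)
    pheno, truth = simulate_phenotypes(offspring, config, rng)
    return SimulatedDataset(
        config, parents, offspring, pedigree, families, actual_sires, pheno, truth
    )
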