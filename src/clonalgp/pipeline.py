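"""End-to-end orchestration: QC → kernels → BLUEs → REML → CV.

`run_full_analysis` drives the whole analysis on in-memory objects and is
what both the CLI and `run_study_reproduction` call. The latter expects the
trial's source tables in the package's CSV dialects under one directory:

    genotypes.csv   wide individual × SNP dosage table
    phenotypes.csv  long record table (individual, site, year, replicate, trait, value)
    pedigree.csv    individual_id, sire_id, dam_id

and recomputes the headline quantities of the clonal-trial analysis: mean
SNP- and pedigree-based relatedness, per-trait ADE variance decomposition
with h2/H2/r_B, model-average h2 across variants, and the family-wise CV
accuracy correlates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .blues import compute_blues_all
from .datatypes import GenotypeMatrix, PedigreeTable
from .gblup import (
    KernelGBLUP,
    cross_trait_stats,
    genotypic_correlation,
    heritabilities,
)
from .kernels import build_A_pedigree, build_Ga, build_Gaa, build_Gd, condition_kernel
from .validation import accuracy_correlates, cv_untested, reference_gegv

logger = logging.getLogger("clonalgp")

__all__ = ["build_kernel_set", "run_full_analysis", "run_study_reproduction", "AnalysisResult"]


def build_kernel_set(geno: GenotypeMatrix) -> dict:
    """Conditioned G_a, G_d, G_aa over the genotyped individuals."""
    Ga = condition_kernel(build_Ga(geno))
    Gd = condition_kernel(build_Gd(geno))
    Gaa = condition_kernel(build_Gaa(build_Ga(geno)))
    return {"a": Ga, "d": Gd, "aa": Gaa}


@dataclass
class AnalysisResult:
    blues: pd.DataFrame
    kernels: dict
    fits: dict  # (trait, variant) -> fitted KernelGBLUP
    varcomps: dict  # trait -> VarianceComponents of the ADE fit
    summary: pd.DataFrame  # per-trait variance-decomposition table
    cv: pd.DataFrame | None = None
    cv_correlates: dict | None = None


def run_full_analysis(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    variants: tuple[str, ...] = ("A", "AD", "ADE"),
    families: dict[str, str] | None = None,
    run_cv: bool = False,
    maf_min: float = 0.05,
    max_missing: float = 0.05,
    **reml_opts,
) -> AnalysisResult:
    """QC + imputation, kernels, stage-1 BLUEs and per-trait REML fits.

    Individuals without any phenotype record are dropped from the analysis
    population (and logged); with ``run_cv`` the untested-at-both-sites
    family CV is run for every trait under every variant.
    """
    geno, report = gio.qc_markers(geno, maf_min=maf_min, max_missing=max_missing)
    logger.info(str(report))
    geno = gio.impute_mean(geno)

    phenotyped = set(pheno["individual_id"].astype(str))
    keep = [i in phenotyped for i in geno.individual_ids]
    dropped = [i for i, k in zip(geno.individual_ids, keep) if not k]
    if dropped:
        logger.info("dropping %d genotyped individuals without phenotypes: %s",
                    len(dropped), dropped[:8])
        geno = GenotypeMatrix(
            [i for i, k in zip(geno.individual_ids, keep) if k],
            list(geno.snp_ids),
            geno.dosages[np.array(keep)],
        )
    pheno = pheno[pheno["individual_id"].isin(set(geno.individual_ids))]

    kernels = build_kernel_set(geno)
    blues = compute_blues_all(pheno)
    traits = sorted(blues["trait"].unique())

    fits, varcomps, rows = {}, {}, []
    cv_rows = []
    for trait in traits:
        tb = blues[blues["trait"] == trait]
        for variant in variants:
            model = KernelGBLUP(kernels=kernels, variant=variant, **reml_opts)
            model.fit(tb[["individual_id", "site"]], tb["blue_value"].to_numpy())
            fits[(trait, variant)] = model
            if variant == "ADE":
                varcomps[trait] = model.varcomps_
                row = {"trait": trait}
                row.update({k: 100 * v for k, v in model.fractions_.items()})
                row["h2"], row["H2"] = model.h2_, model.H2_
                row["rB"] = model.rB_
                row["loglik"] = model.loglik_
                row["converged"] = model.converged_
                rows.append(row)
        if run_cv and families is not None:
            ref = fits[(trait, "ADE")].gegv_
            for variant in variants:
                res = cv_untested(tb, kernels, variant, families, reference=ref, **reml_opts)
                res["trait"] = trait
                res["variant"] = variant
                cv_rows.append(res)

    summary = pd.DataFrame(rows).set_index("trait") if rows else pd.DataFrame()
    cv = pd.concat(cv_rows, ignore_index=True) if cv_rows else None
    correlates = None
    if cv is not None and "ADE" in variants:
        ade = cv[cv["variant"] == "ADE"]
        h2s = {t: fits[(t, "ADE")].h2_ for t in traits}
        correlates = accuracy_correlates(ade, h2s)
    return AnalysisResult(blues, kernels, fits, varcomps, summary, cv, correlates)


def run_study_reproduction(data_dir: str | Path, run_cv: bool = True) -> dict:
    """Reproduce the headline full-data quantities from deposited trial data.

    ``data_dir`` must hold ``genotypes.csv``, ``phenotypes.csv`` and
    ``pedigree.csv`` in the package dialects. Returns a dict with the mean
    SNP-based relatedness, the mean pedigree relatedness among parents, the
    per-trait variance-decomposition table, model-average h2 per variant,
    cross-trait derived statistics, and (optionally) CV accuracy correlates.
    """
    data_dir = Path(data_dir)
    for name in ("genotypes.csv", "phenotypes.csv", "pedigree.csv"):
        if not (data_dir / name).exists():
            raise FileNotFoundError(
                f"study data file {name} not found under {data_dir}; the trial's "
                "deposited supplementary tables must be converted to the package "
                "CSV dialects and placed there"
            )
    geno = gio.read_genotypes(data_dir / "genotypes.csv")
    pheno = gio.read_phenotypes(data_dir / "phenotypes.csv")
    ped = gio.read_pedigree(data_dir / "pedigree.csv")

    # families = offspring grouped by (sire, dam); parents = recorded parents
    genotyped = set(geno.individual_ids)
    fam_of: dict[str, str] = {}
    parents: set[str] = set()
    for ind, s, d in zip(ped.individual_ids, ped.sires, ped.dams):
        if s is not None and d is not None and ind in genotyped:
            fam_of[ind] = f"{s}x{d}"
            parents.update((s, d))

    result = run_full_analysis(geno, pheno, families=fam_of, run_cv=run_cv)

    Ga = result.kernels["a"]
    A = build_A_pedigree(ped)
    parent_A = A.subset(sorted(parents & set(ped.individual_ids)))

    out = {
        "mean_snp_relatedness": float(Ga.off_diagonal().mean()),
        "mean_parent_pedigree_relatedness": float(parent_A.off_diagonal().mean()),
        "per_trait": result.summary,
        "derived": cross_trait_stats(result.varcomps),
    }
    for variant in ("A", "AD", "ADE"):
        h2s = [
            heritabilities(result.fits[(t, variant)].varcomps_)[0]
            for t in result.varcomps
        ]
        out[f"mean_h2_{variant}"] = float(np.mean(h2s))
    if result.cv_correlates is not None:
        out.update(result.cv_correlates)
    return out
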