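"""Stage 1 of the two-step analysis: adjusted phenotypes (BLUEs).

Clonal-replicate × year records are collapsed to a single adjusted value per
individual per site per trait by ordinary least squares with genotype, year
and replicate all fixed: ``value ~ genotype + year + replicate`` fitted within
site. The genotype estimate is a BLUE (unshrunk); year and replicate enter as
additive main effects. BLUEs are re-centred so their mean equals the site
trait mean, which makes them directly comparable across sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["compute_blues", "compute_blues_all", "site_trait_summary"]


def _design(values: pd.Series, levels: list) -> np.ndarray:
    """Treatment-coded dummies (first level dropped)."""
    cols = [(values == lev).to_numpy(float) for lev in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(values), 0))


def compute_blues(pheno: pd.DataFrame, trait: str, site: str) -> pd.DataFrame:
    """BLUEs for one trait at one site.

    Returns a frame with columns ``individual_id, site, trait, blue_value,
    n_records_supporting``. Genotypes with a single record still receive a
    BLUE: their record adjusted by the year/replicate estimates borrowed from
    the rest of the trial. A design in which some year or replicate level is
    confounded with a single genotype is rejected by name.
    """
    sub = pheno[(pheno["trait"] == trait) & (pheno["site"] == site)]
    if len(sub) == 0:
        raise ValueError(f"no records for trait {trait!r} at site {site!r}")
    sub = sub.reset_index(drop=True)
    genos = sorted(sub["individual_id"].unique())
    years = sorted(sub["year"].unique())
    reps = sorted(sub["replicate"].unique())

    for factor, levels in (("year", years), ("replicate", reps)):
        for lev in levels:
            n_geno = sub.loc[sub[factor] == lev, "individual_id"].nunique()
            if len(levels) > 1 and n_geno < 2:
                raise ValueError(
                    f"confounded design: {factor} level {lev!r} observed on "
                    f"fewer than two genotypes"
                )

    y = sub["value"].to_numpy(float)
    Xg = _design(sub["individual_id"], genos)
    Xy = _design(sub["year"], years)
    Xr = _design(sub["replicate"], reps)
    X = np.column_stack([np.ones(len(sub)), Xg, Xy, Xr])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design after confounding checks")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    # genotype effect (treatment coding: first genotype's effect is 0)
    g_eff = np.concatenate([[0.0], beta[1 : len(genos)]])
    blue = g_eff - g_eff.mean() + y.mean()

    counts = sub.groupby("individual_id").size()
    return pd.DataFrame(
        {
            "individual_id": genos,
            "site": site,
            "trait": trait,
            "blue_value": blue,
            "n_records_supporting": counts.loc[genos].to_numpy(),
        }
    )


def compute_blues_all(pheno: pd.DataFrame) -> pd.DataFrame:
    """BLUEs for every (trait, site) combination present in the records."""
    parts = [
        compute_blues(pheno, trait, site)
        for trait in sorted(pheno["trait"].unique())
        for site in sorted(pheno["site"].unique())
        if len(pheno[(pheno["trait"] == trait) & (pheno["site"] == site)]) > 0
    ]
    return pd.concat(parts, ignore_index=True)


def site_trait_summary(pheno: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Per site × trait mean, coefficient of variation, and site-difference flag.

    CV% = sd / mean × 100 over all records at the site. For each trait a
    two-sample Welch test compares the two (or first two) sites; the
    significance flag is attached to every row of that trait.
    """
    rows = []
    for trait, tsub in pheno.groupby("trait"):
        sites = sorted(tsub["site"].unique())
        sig = False
        if len(sites) >= 2:
            x = tsub.loc[tsub["site"] == sites[0], "value"]
            y = tsub.loc[tsub["site"] == sites[1], "value"]
            if x.std() > 0 or y.std() > 0:
                sig = stats.ttest_ind(x, y, equal_var=False).pvalue < alpha
        for site in sites:
            vals = tsub.loc[tsub["site"] == site, "value"]
            mean = float(vals.mean())
            cv = float(vals.std(ddof=1) / mean * 100.0) if mean != 0 else np.nan
            rows.append(
                {
                    "trait": trait,
                    "site": site,
                    "mean": mean,
                    "cv_percent": cv,
                    "n_records": len(vals),
                    "site_difference_significant": bool(sig),
                }
            )
    return pd.DataFrame(rows)
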