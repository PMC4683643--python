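"""Leave-one-family-out cross-validation of genomic prediction.

Each full-sib family is held out in turn as the validation population (VP)
and the model is refitted on the remaining families (training population,
TP) — variance components re-estimated within each fold, so no information
leaks from the held-out records. Two strategies mirror practical breeding
situations:

* ``untested_both_sites`` — VP records are removed at every site; the
  prediction rests entirely on the TP through the kernel cross-covariance.
* ``tested_one_site`` — VP records are removed at one target site only; the
  VP's own records at the other site(s) inform its prediction there.

Accuracy is the Pearson correlation between the predicted genetic values
(GEGV = a + d + i, a + d, or a, per model variant) and the reference
BLUP-GV of the VP individuals taken from the all-data ADE fit; bias is the
slope of the regression of BLUP-GV on GEGV (1 = unbiased).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import RelationshipMatrix
from .gblup import KernelGBLUP, assemble_design, reml_fit

__all__ = [
    "cv_untested",
    "cv_single_site",
    "accuracy_correlates",
    "reference_gegv",
]

CV_COLUMNS = [
    "family_id",
    "strategy",
    "target_site",
    "trait",
    "accuracy",
    "bias",
    "n_validation",
    "mean_tp_vp_relatedness",
]


def _fit_variant(blues: pd.DataFrame, kernels, variant: str, **reml_opts) -> KernelGBLUP:
    model = KernelGBLUP(kernels=kernels, variant=variant, **reml_opts)
    model.fit(blues[["individual_id", "site"]], blues["blue_value"].to_numpy())
    return model


def reference_gegv(blues: pd.DataFrame, kernels, **reml_opts) -> pd.Series:
    """BLUP-GV (a + d + i) per individual from the all-data ADE fit — the
    reference against which every validated model variant is scored."""
    return _fit_variant(blues, kernels, "ADE", **reml_opts).gegv_


def _ga_matrix(kernels) -> tuple[np.ndarray, list[str]]:
    Ga = kernels["a"]
    if isinstance(Ga, RelationshipMatrix):
        return Ga.values, list(Ga.ids)
    raise ValueError("kernels['a'] must be a RelationshipMatrix with ids for CV")


def _accuracy_bias(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    if np.std(pred) == 0 or np.std(ref) == 0:
        return float("nan"), float("nan")
    acc = float(np.corrcoef(pred, ref)[0, 1])
    slope = float(np.cov(ref, pred, ddof=1)[0, 1] / np.var(pred, ddof=1))
    return acc, slope


def _one_fold(
    blues: pd.DataFrame,
    kernels,
    variant: str,
    fam: str,
    members: list[str],
    ref: pd.Series,
    mask: pd.Series,
    strategy: str,
    target_site: str | None,
    reml_opts,
) -> dict | None:
    train = blues[~mask]
    val_ids = sorted(set(members) & set(blues["individual_id"]))
    if len(val_ids) < 3:
        warnings.warn(f"family {fam}: fewer than 3 members with records, fold skipped", stacklevel=2)
        return None
    if mask.sum() == 0:
        return None  # nothing to mask (family absent at the target site)
    model = _fit_variant(train, kernels, variant, **reml_opts)
    pred = model.genetic_values(val_ids).to_numpy()
    refv = ref.loc[val_ids].to_numpy()
    acc, bias = _accuracy_bias(pred, refv)

    Gav, ids = _ga_matrix(kernels)
    index = {v: i for i, v in enumerate(ids)}
    vi = [index[i] for i in val_ids]
    ti = [index[i] for i in sorted(set(train["individual_id"]))if i not in set(val_ids)]
    rel = float(Gav[np.ix_(vi, ti)].mean()) if ti else float("nan")
    return {
        "family_id": fam,
        "strategy": strategy,
        "target_site": target_site,
        "trait": blues["trait"].iloc[0] if "trait" in blues else "",
        "accuracy": acc,
        "bias": bias,
        "n_validation": len(val_ids),
        "mean_tp_vp_relatedness": rel,
    }


def cv_untested(
    blues: pd.DataFrame,
    kernels,
    variant: str,
    families: dict[str, str],
    reference: pd.Series | None = None,
    **reml_opts,
) -> pd.DataFrame:
    """17-fold (one per family) CV with the validation family unobserved at
    every site. Returns one row per family with accuracy, bias, validation
    size and mean TP–VP additive relatedness."""
    if reference is None:
        reference = reference_gegv(blues, kernels, **reml_opts)
    fam_series = blues["individual_id"].map(families)
    if fam_series.isna().any():
        raise KeyError("family label missing for some individuals in blues")
    rows = []
    for fam in sorted(set(families.values())):
        members = [i for i, f in families.items() if f == fam]
        mask = fam_series == fam
        row = _one_fold(
            blues, kernels, variant, fam, members, reference, mask,
            "untested_both_sites", None, reml_opts,
        )
        if row is not None:
            rows.append(row)
    return pd.DataFrame(rows, columns=CV_COLUMNS)


def cv_single_site(
    blues: pd.DataFrame,
    kernels,
    variant: str,
    families: dict[str, str],
    target_site: str,
    reference: pd.Series | None = None,
    **reml_opts,
) -> pd.DataFrame:
    """Family-wise CV with the validation family masked at ``target_site``
    only; its records at the other site(s) stay in the training data."""
    if reference is None:
        reference = reference_gegv(blues, kernels, **reml_opts)
    fam_series = blues["individual_id"].map(families)
    if fam_series.isna().any():
        raise KeyError("family label missing for some individuals in blues")
    rows = []
    for fam in sorted(set(families.values())):
        members = [i for i, f in families.items() if f == fam]
        mask = (fam_series == fam) & (blues["site"].astype(str) == str(target_site))
        row = _one_fold(
            blues, kernels, variant, fam, members, reference, mask,
            "tested_one_site", str(target_site), reml_opts,
        )
        if row is not None:
            rows.append(row)
    return pd.DataFrame(rows, columns=CV_COLUMNS)


def accuracy_correlates(
    results: pd.DataFrame, h2_by_trait: dict[str, float] | None = None
) -> dict:
    """Correlates of prediction accuracy.

    ``r_relatedness``: Pearson correlation, across validation families, of
    per-family accuracy (averaged over traits) with mean TP–VP relatedness.
    ``r_heritability``: correlation, across traits, of per-trait mean
    accuracy with the trait's narrow-sense heritability (requires
    ``h2_by_trait``). Either is NaN when fewer than 3 points or degenerate.
    """

    def _cor(x: np.ndarray, y: np.ndarray) -> float:
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    by_fam = results.groupby("family_id").agg(
        accuracy=("accuracy", "mean"), rel=("mean_tp_vp_relatedness", "mean")
    )
    out = {"r_relatedness": _cor(by_fam["rel"].to_numpy(), by_fam["accuracy"].to_numpy())}
    if h2_by_trait is not None:
        by_trait = results.groupby("trait")["accuracy"].mean()
        traits = [t for t in by_trait.index if t in h2_by_trait]
        out["r_heritability"] = _cor(
            np.array([h2_by_trait[t] for t in traits]),
            by_trait.loc[traits].to_numpy(),
        )
    else:
        out["r_heritability"] = float("nan")
    return out
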