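"""Readers, writers, marker QC and mean imputation.

File dialects (all plain CSV, comma-separated unless a ``sep`` is given):

* genotypes — wide: first column ``individual_id``, one column per SNP,
  cells in {0,1,2} or an unknown token (``NA``, empty, ``-9``) for missing;
* phenotypes — long: ``individual_id,site,year,replicate,trait,value``;
* pedigree — ``individual_id,sire_id,dam_id`` with empty/``0``/``NA`` for an
  unknown parent.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    PHENOTYPE_COLUMNS,
    GenotypeMatrix,
    PedigreeTable,
    QCReport,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "qc_markers",
    "impute_mean",
]

MISSING_TOKENS = {"", "na", "nan", "-9", ".", "none"}


def read_genotypes(path: str | Path, sep: str = ",") -> GenotypeMatrix:
    """Parse a wide genotype CSV into a :class:`GenotypeMatrix`.

    Unknown tokens map to missing; any cell that is neither a valid dosage nor
    a recognized missing token raises a parse error naming its row and column.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus SNP columns")
    ind_col = df.columns[0]
    snp_ids = [str(c) for c in df.columns[1:]]
    individual_ids = [str(v) for v in df[ind_col]]
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    dosages = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = str(raw[i, j]).strip()
            if tok.lower() in MISSING_TOKENS:
                dosages[i, j] = np.nan
                continue
            try:
                val = float(tok)
            except ValueError:
                val = np.nan
            # fractional dosages in [0, 2] are legitimate (mean-imputed)
            if not 0.0 <= val <= 2.0:
                raise ValueError(
                    f"{path}: invalid dosage {tok!r} for individual "
                    f"{individual_ids[i]!r}, SNP {snp_ids[j]!r}"
                )
            dosages[i, j] = val
    return GenotypeMatrix(individual_ids, snp_ids, dosages)


def write_genotypes(geno: GenotypeMatrix, path: str | Path, sep: str = ",") -> None:
    dos = geno.dosages
    # keep integer look for called genotypes so a round-trip is exact
    cells = np.where(np.isnan(dos), "NA", np.char.mod("%.10g", np.nan_to_num(dos)))
    df = pd.DataFrame(cells, columns=geno.snp_ids)
    df.insert(0, "individual_id", geno.individual_ids)
    df.to_csv(path, sep=sep, index=False)


def read_phenotypes(
    path: str | Path,
    sep: str = ",",
    allowed_sites: list[str] | None = None,
) -> pd.DataFrame:
    """Read a long-format phenotype table; validate keys and uniqueness."""
    df = pd.read_csv(path, sep=sep)
    missing_cols = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    df = df[PHENOTYPE_COLUMNS].copy()
    for c in ("individual_id", "site", "trait"):
        df[c] = df[c].astype(str)
    df["value"] = pd.to_numeric(df["value"])
    if not np.isfinite(df["value"]).all():
        raise ValueError(f"{path}: non-finite phenotype values")
    key = ["individual_id", "site", "year", "replicate", "trait"]
    dup = df.duplicated(key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].to_dict()
        raise ValueError(f"{path}: duplicate phenotype record {first}")
    if allowed_sites is not None:
        bad = set(df["site"]) - set(allowed_sites)
        if bad:
            raise ValueError(f"{path}: unknown site(s) {sorted(bad)}")
    return df


def write_phenotypes(pheno: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    pheno[PHENOTYPE_COLUMNS].to_csv(path, sep=sep, index=False)


def read_pedigree(path: str | Path, sep: str = ",") -> PedigreeTable:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    needed = {"individual_id", "sire_id", "dam_id"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: pedigree needs columns {sorted(needed)}")

    def _parent(tok: str) -> str | None:
        tok = str(tok).strip()
        return None if tok.lower() in MISSING_TOKENS or tok == "0" else tok

    records = [
        (str(r.individual_id), _parent(r.sire_id), _parent(r.dam_id))
        for r in df.itertuples(index=False)
    ]
    return PedigreeTable.from_records(records)


def write_pedigree(ped: PedigreeTable, path: str | Path, sep: str = ",") -> None:
    ped.to_frame().to_csv(path, sep=sep, index=False)


def qc_markers(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs by missing-call rate, then by minor allele frequency.

    Defaults mirror common array-QC practice for this kind of panel: discard
    SNPs with more than 5% missing calls, then SNPs with MAF < 0.05. The
    filters are applied in that order, so the reported per-criterion counts
    are sequential, and the operation is idempotent.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    n_in = geno.n_snps
    keep_miss = geno.missing_rate() <= max_missing
    n_rm_miss = int((~keep_miss).sum())
    sub = GenotypeMatrix(
        list(geno.individual_ids),
        [s for s, k in zip(geno.snp_ids, keep_miss) if k],
        geno.dosages[:, keep_miss],
    )
    keep_maf = sub.maf() >= maf_min
    n_rm_maf = int((~keep_maf).sum())
    out = GenotypeMatrix(
        list(sub.individual_ids),
        [s for s, k in zip(sub.snp_ids, keep_maf) if k],
        sub.dosages[:, keep_maf],
    )
    if out.n_snps == 0:
        warnings.warn("marker QC removed every SNP", stacklevel=2)
    return out, QCReport(n_in, n_rm_miss, n_rm_maf, out.n_snps)


def impute_mean(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage with 2p for its SNP.

    Mean imputation preserves the observed allele frequency and the per-SNP
    mean dosage, which is all the relationship-matrix construction needs.
    A SNP with no observed calls cannot be imputed and raises.
    """
    dos = geno.dosages.copy()
    all_missing = np.isnan(dos).all(axis=0)
    if all_missing.any():
        bad = [s for s, b in zip(geno.snp_ids, all_missing) if b]
        raise ValueError(f"cannot impute all-missing SNP(s): {bad[:5]}")
    p = geno.compute_allele_freqs()
    rows, cols = np.nonzero(np.isnan(dos))
    dos[rows, cols] = 2.0 * p[cols]
    return GenotypeMatrix(list(geno.individual_ids), list(geno.snp_ids), dos)
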