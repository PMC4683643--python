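"""Genomic and pedigree relationship matrices.

Additive kernel (VanRaden scaling): centre dosages at twice the observed
allele frequency, ``M[i,j] = x_ij - 2 p_j``, and set

    G_a = M M' / sum_j 2 p_j q_j .

Dominance kernel: code heterozygosity against its Hardy–Weinberg expectation,
``H[i,j] = het_ij - 2 p_j q_j`` with ``het`` the 0/1 heterozygote indicator,
and

    G_d = H H' / sum_j 2 p_j q_j (1 - 2 p_j q_j) .

Additive-by-additive epistatic kernel: the Hadamard (element-wise) square of
G_a, which is PSD whenever G_a is (Schur product theorem).

Pedigree counterparts use the tabular (recursive) numerator relationship
method and the classical non-inbred dominance relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    VALID_KERNEL_KINDS,
    GenotypeMatrix,
    PedigreeTable,
    RelationshipMatrix,
)

__all__ = [
    "build_Ga",
    "build_Gd",
    "build_Gaa",
    "build_A_pedigree",
    "build_D_pedigree",
    "condition_kernel",
    "relatedness_summary",
    "pca_genotypes",
    "write_kernel",
    "read_kernel",
    "RelatednessSummary",
]


def _check_complete(geno: GenotypeMatrix) -> None:
    if np.isnan(geno.dosages).any():
        raise ValueError("genotype matrix has missing dosages; impute first")
    if geno.n_snps < 1:
        raise ValueError("no SNPs")


def build_Ga(
    geno: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """Additive genomic relationship matrix.

    Centring frequencies default to the observed sample frequencies; pass
    ``freqs`` to centre on known base-population frequencies instead.
    """
    _check_complete(geno)
    p = geno.compute_allele_freqs() if freqs is None else np.asarray(freqs, float)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: additive denominator is zero")
    M = geno.dosages - 2.0 * p
    G = (M @ M.T) / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix(list(geno.individual_ids), G, "additive_genomic")


def build_Gd(
    geno: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """Dominance genomic relationship matrix from heterozygosity codings."""
    _check_complete(geno)
    p = geno.compute_allele_freqs() if freqs is None else np.asarray(freqs, float)
    twopq = 2.0 * p * (1.0 - p)
    denom = float(np.sum(twopq * (1.0 - twopq)))
    if denom <= 0:
        raise ValueError("dominance denominator is zero")
    # imputed fractional dosages are treated as homozygous (het indicator 0)
    het = np.where(np.isclose(geno.dosages, 1.0), 1.0, 0.0)
    H = het - twopq
    G = (H @ H.T) / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix(list(geno.individual_ids), G, "dominance_genomic")


def build_Gaa(Ga: RelationshipMatrix) -> RelationshipMatrix:
    """Additive×additive epistatic kernel: the Hadamard square of G_a."""
    if Ga.kind != "additive_genomic":
        raise ValueError(f"expected an additive_genomic kernel, got {Ga.kind!r}")
    return RelationshipMatrix(list(Ga.ids), Ga.values * Ga.values, "epistatic_genomic")


def build_A_pedigree(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix A via the tabular method.

    A_ii = 1 + A(sire, dam)/2; A_ij = (A(j, sire_i) + A(j, dam_i)) / 2 with
    unknown parents contributing zero. Requires a topologically sorted
    pedigree, which :class:`PedigreeTable` guarantees.
    """
    n = len(ped)
    index = {v: i for i, v in enumerate(ped.individual_ids)}
    A = np.zeros((n, n))
    for i, (ind, s, d) in enumerate(zip(ped.individual_ids, ped.sires, ped.dams)):
        si = index[s] if s is not None else None
        di = index[d] if d is not None else None
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
        contrib = np.zeros(i)
        if si is not None:
            contrib += A[:i, si]
        if di is not None:
            contrib += A[:i, di]
        A[:i, i] = A[i, :i] = 0.5 * contrib
    return RelationshipMatrix(list(ped.individual_ids), A, "additive_pedigree")


def build_D_pedigree(ped: PedigreeTable, A: RelationshipMatrix) -> RelationshipMatrix:
    """Dominance relationship matrix under the non-inbred simplification.

    D_ij = (A(s_i,s_j) A(d_i,d_j) + A(s_i,d_j) A(d_i,s_j)) / 4 off the
    diagonal and D_ii = 1.
    """
    if A.ids != ped.individual_ids:
        raise ValueError("A matrix ids do not match pedigree")
    n = len(ped)
    index = {v: i for i, v in enumerate(ped.individual_ids)}
    Av = A.values

    def rel(x: str | None, y: str | None) -> float:
        if x is None or y is None:
            return 0.0
        return Av[index[x], index[y]]

    D = np.eye(n)
    for i in range(n):
        si, di = ped.sires[i], ped.dams[i]
        for j in range(i):
            sj, dj = ped.sires[j], ped.dams[j]
            D[i, j] = D[j, i] = 0.25 * (
                rel(si, sj) * rel(di, dj) + rel(si, dj) * rel(di, sj)
            )
    return RelationshipMatrix(list(ped.individual_ids), D, "dominance_pedigree")


def condition_kernel(
    K: RelationshipMatrix, epsilon: float = 1e-6
) -> RelationshipMatrix:
    """Bend a kernel to positive semi-definiteness by diagonal inflation.

    If the smallest eigenvalue is negative, add ``|lambda_min| + epsilon`` to
    the diagonal and flag the result; PSD inputs pass through unchanged.
    """
    lam_min = float(np.linalg.eigvalsh(K.values)[0])
    if lam_min >= 0:
        return K
    bent = K.values + (abs(lam_min) + epsilon) * np.eye(K.n)
    return RelationshipMatrix(list(K.ids), bent, K.kind, bending_applied=True)


def write_kernel(K: RelationshipMatrix, path) -> None:
    """Labeled square CSV (ids as header and index)."""
    df = K.to_frame()
    df.index.name = K.kind
    df.to_csv(path)


def read_kernel(path, kind: str = "additive_genomic") -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    kind = df.index.name if df.index.name in VALID_KERNEL_KINDS else kind
    return RelationshipMatrix(
        [str(c) for c in df.columns], df.to_numpy(float), kind
    )


@dataclass
class RelatednessSummary:
    mean_off_diagonal: float
    mean_including_diagonal: float
    quantiles: dict[str, float]
    within_family: pd.Series | None = None
    between_family: pd.DataFrame | None = None


def relatedness_summary(
    K: RelationshipMatrix, families: dict[str, str] | None = None
) -> RelatednessSummary:
    """Mean/quantile summaries of pairwise relationships.

    With a family map (individual -> family label), also reports the mean
    relationship within each recorded family and between each family pair.
    Both diagonal conventions are reported since "average relationship" is
    quoted either way in the literature.
    """
    if K.n < 2:
        raise ValueError("need at least two individuals")
    off = K.off_diagonal()
    qs = {f"q{int(q * 100)}": float(np.quantile(off, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)}
    summary = RelatednessSummary(
        mean_off_diagonal=float(off.mean()),
        mean_including_diagonal=float(K.values[np.triu_indices(K.n)].mean()),
        quantiles=qs,
    )
    if families is not None:
        fam = np.array([families[i] for i in K.ids])
        labels = sorted(set(fam))
        within = {}
        between = pd.DataFrame(np.nan, index=labels, columns=labels)
        for a_i, fa in enumerate(labels):
            ia = np.nonzero(fam == fa)[0]
            if len(ia) > 1:
                block = K.values[np.ix_(ia, ia)]
                within[fa] = float(block[np.triu_indices(len(ia), k=1)].mean())
            for fb in labels[: a_i + 1]:
                ib = np.nonzero(fam == fb)[0]
                if fa == fb:
                    continue
                val = float(K.values[np.ix_(ia, ib)].mean())
                between.loc[fa, fb] = between.loc[fb, fa] = val
        summary.within_family = pd.Series(within, name="within_family_mean")
        summary.between_family = between
    return summary


def pca_genotypes(
    geno: GenotypeMatrix, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates of individuals from their centred genotypes.

    Eigendecomposition of the centred genotype covariance (equivalently of
    G_a up to scale); returns the first k coordinate vectors and the fraction
    of variance each explains.
    """
    if geno.n_individuals < 2:
        raise ValueError("need at least two individuals")
    G = build_Ga(geno).values
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(n_components, geno.n_individuals)
    vals_pos = np.clip(vals, 0.0, None)
    coords = vecs[:, :k] * np.sqrt(vals_pos[:k])
    explained = vals_pos[:k] / vals_pos.sum() if vals_pos.sum() > 0 else np.zeros(k)
    df = pd.DataFrame(
        coords, index=geno.individual_ids, columns=[f"PC{i+1}" for i in range(k)]
    )
    return df, explained
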