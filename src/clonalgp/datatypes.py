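"""Core in-memory containers shared across the package.

The analysis population is a set of clonally replicated individuals genotyped
at biallelic SNPs and phenotyped over sites × years × clonal replicates.
Containers here are thin, validated wrappers around numpy arrays and pandas
frames; heavy computation lives in the modules that consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PedigreeTable",
    "RelationshipMatrix",
    "VarianceComponents",
    "QCReport",
    "PHENOTYPE_COLUMNS",
    "COMPONENT_KEYS",
]

#: canonical long-format phenotype columns, one row per clonal-replicate record
PHENOTYPE_COLUMNS = ["individual_id", "site", "year", "replicate", "trait", "value"]

#: the seven variance components of the full ADE + site-interaction model
COMPONENT_KEYS = ("a", "d", "aa", "a_site", "d_site", "aa_site", "e")


@dataclass
class GenotypeMatrix:
    """n × m allele-dosage matrix with per-SNP allele frequencies.

    Dosages count copies of the "B" allele (0, 1, 2); missing calls are NaN.
    ``allele_freqs[j]`` is the observed frequency of the counted allele at SNP
    j, computed over non-missing entries. All kernel formulas downstream are
    invariant to which allele is counted at any SNP.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    allele_freqs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.snp_ids) != m:
            raise ValueError("id lists do not match dosage dimensions")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        # imputed matrices carry fractional dosages; only freshly parsed data
        # are required to be {0,1,2,NaN} — enforced by the reader, not here.
        del valid
        if self.allele_freqs is None:
            self.allele_freqs = self.compute_allele_freqs()
        else:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def compute_allele_freqs(self) -> np.ndarray:
        """Observed frequency of the counted allele per SNP, ignoring missing."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.compute_allele_freqs()
        return np.minimum(p, 1.0 - p)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individual_ids),
            list(self.snp_ids),
            self.dosages.copy(),
            self.allele_freqs.copy(),
        )


@dataclass
class PedigreeTable:
    """Three-column pedigree, topologically sorted (parents before offspring).

    ``sire`` / ``dam`` are None for founders. Construction validates acyclicity
    and sortedness; use :func:`clonalgp.io.read_pedigree` or
    :meth:`from_records` to build one from unsorted records.
    """

    individual_ids: list[str]
    sires: list[str | None]
    dams: list[str | None]

    def __post_init__(self) -> None:
        if not (len(self.individual_ids) == len(self.sires) == len(self.dams)):
            raise ValueError("pedigree column lengths differ")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual in pedigree")
        seen: set[str] = set()
        for ind, s, d in zip(self.individual_ids, self.sires, self.dams):
            for par in (s, d):
                if par is not None and par not in seen:
                    raise ValueError(
                        f"pedigree not topologically sorted: parent {par!r} of "
                        f"{ind!r} does not precede it"
                    )
            seen.add(ind)

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str | None, str | None]]
    ) -> "PedigreeTable":
        """Topologically sort (individual, sire, dam) records; raise on cycles."""
        import graphlib

        parents = {ind: (s, d) for ind, s, d in records}
        graph: dict[str, set[str]] = {}
        for ind, s, d in records:
            deps = {p for p in (s, d) if p is not None}
            graph[ind] = deps
            for p in deps:
                graph.setdefault(p, set())
        try:
            order = list(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as exc:
            raise ValueError(f"cyclic pedigree: {exc.args[1]}") from exc
        ids, sires, dams = [], [], []
        for ind in order:
            s, d = parents.get(ind, (None, None))
            ids.append(ind)
            sires.append(s)
            dams.append(d)
        return cls(ids, sires, dams)

    def __len__(self) -> int:
        return len(self.individual_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_ids,
                "sire_id": [s if s is not None else "" for s in self.sires],
                "dam_id": [d if d is not None else "" for d in self.dams],
            }
        )


VALID_KERNEL_KINDS = (
    "additive_genomic",
    "dominance_genomic",
    "epistatic_genomic",
    "additive_pedigree",
    "dominance_pedigree",
)


@dataclass
class RelationshipMatrix:
    """Symmetric n × n relationship kernel with a provenance tag."""

    ids: list[str]
    values: np.ndarray
    kind: str
    bending_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match id list")
        if self.kind not in VALID_KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        index = {v: i for i, v in enumerate(self.ids)}
        idx = np.array([index[i] for i in ids])
        return RelationshipMatrix(
            list(ids), self.values[np.ix_(idx, idx)], self.kind, self.bending_applied
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class VarianceComponents:
    """Variance components of the site-interaction GBLUP model.

    ``sigma2`` maps component keys (subset of :data:`COMPONENT_KEYS`) to
    nonnegative variances in squared trait units. Derived ratios — narrow- and
    broad-sense heritability and the between-site genotypic correlation — are
    computed lazily from the map; components absent under reduced model
    variants count as zero.
    """

    sigma2: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.sigma2) - set(COMPONENT_KEYS)
        if unknown:
            raise ValueError(f"unknown variance components: {sorted(unknown)}")
        for k, v in self.sigma2.items():
            if v < 0:
                raise ValueError(f"negative variance for component {k!r}")

    def get(self, key: str) -> float:
        return float(self.sigma2.get(key, 0.0))

    @property
    def total(self) -> float:
        return float(sum(self.sigma2.values()))

    @property
    def fractions(self) -> dict[str, float]:
        tot = self.total
        if tot <= 0:
            raise ZeroDivisionError("total phenotypic variance is zero")
        return {k: v / tot for k, v in self.sigma2.items()}

    @property
    def genetic(self) -> float:
        """Total main genetic variance sigma^2_G = sigma^2_a + sigma^2_d + sigma^2_aa."""
        return self.get("a") + self.get("d") + self.get("aa")

    @property
    def interaction(self) -> float:
        """Total genetic-by-site variance."""
        return self.get("a_site") + self.get("d_site") + self.get("aa_site")

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "VarianceComponents":
        return cls({k: float(v) for k, v in values.items()})

    def scaled(self, factor: float) -> "VarianceComponents":
        return replace(self, sigma2={k: v * factor for k, v in self.sigma2.items()})


@dataclass
class QCReport:
    """Counts of SNPs removed by each marker-QC criterion, in order applied."""

    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_retained: int

    def __str__(self) -> str:
        return (
            f"QC: {self.n_input} SNPs in, {self.n_removed_missing} removed for "
            f"missingness, {self.n_removed_maf} removed for MAF, "
            f"{self.n_retained} retained"
        )
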