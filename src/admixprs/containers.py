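"""In-memory data model shared by every pipeline stage.

The central container is :class:`GenotypeMatrix`, an individuals x SNPs
matrix of alternate-allele counts with per-SNP allele metadata (REF/ALT
bases and, when known, the ancestral state).  Missing genotype calls are
stored as the sentinel :data:`MISSING` (-1), which is deliberately distinct
from a homozygous-reference call of 0.

Coordinates are 1-based throughout, as in VCF; nothing downstream
reinterprets them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid genotype call (``./.`` in VCF).
MISSING: int = -1

#: The fixed vocabulary of GWAS discovery-cohort ancestry labels.
COHORT_ANCESTRY_LABELS = frozenset(
    {
        "African",
        "East Asian",
        "European",
        "Hispanic/Latino",
        "Native American",
        "Multi-ethnic",
        "Admixed American",
    }
)

#: Continental ancestry components of the three-way admixture model.
ANCESTRY_COMPONENTS = ("African", "European", "NativeAmerican")


@dataclass
class VariantRecord:
    """One biallelic SNP as read from a VCF record.

    ``genotypes`` holds per-individual alternate-allele counts in
    {0, 1, 2} with :data:`MISSING` for no-calls.  ``ancestral`` is the
    ancestral base (matching ``ref`` or ``alt``) or ``None`` when unknown.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    ancestral: str | None
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")
        if self.ancestral is not None and self.ancestral not in (self.ref, self.alt):
            raise ValueError(
                f"{self.id}: ancestral allele {self.ancestral!r} matches neither "
                f"ref nor alt"
            )
        g = np.asarray(self.genotypes)
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{self.id}: genotype values outside {{0,1,2,missing}}")


@dataclass
class SnpAssociation:
    """A trait-associated variant from a GWAS association table."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    cohort_ancestry: frozenset[str] = frozenset()
    effect_polarity: str = "unknown"  # "derived" | "ancestral" | "unknown"
    weight: float | None = None  # accepted but unused by the unweighted score

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.id}: effect and other alleles are identical")
        unknown = set(self.cohort_ancestry) - COHORT_ANCESTRY_LABELS
        if unknown:
            raise ValueError(f"{self.id}: unknown cohort ancestry label(s) {unknown}")
        if self.effect_polarity not in ("derived", "ancestral", "unknown"):
            raise ValueError(f"{self.id}: bad effect_polarity {self.effect_polarity!r}")


@dataclass
class AncestryProfile:
    """Per-individual fractions of the K=3 continental ancestries.

    Fractions must lie in [0, 1] and sum to 1 within 1e-6.
    """

    individual_id: str
    f_African: float
    f_European: float
    f_NativeAmerican: float

    def __post_init__(self) -> None:
        fracs = (self.f_African, self.f_European, self.f_NativeAmerican)
        if any(f < 0.0 or f > 1.0 for f in fracs):
            raise ValueError(f"{self.individual_id}: ancestry fraction outside [0,1]")
        if abs(sum(fracs) - 1.0) > 1e-6:
            raise ValueError(
                f"{self.individual_id}: ancestry fractions sum to {sum(fracs)!r}, not 1"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.f_African, self.f_European, self.f_NativeAmerican])


class GenotypeMatrix:
    """Individuals x SNPs alternate-allele dosage matrix with SNP metadata.

    Parameters
    ----------
    dosages
        Integer array of shape (n_individuals, n_snps); entries in
        {0, 1, 2} or :data:`MISSING`.
    individuals
        Ordered individual identifiers (rows).
    snps
        DataFrame with one row per SNP (columns ``id``, ``chrom``, ``pos``,
        ``ref``, ``alt``, ``ancestral``); ``ancestral`` is a base or None.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        individuals: Sequence[str],
        snps: pd.DataFrame,
    ) -> None:
        dosages = np.asarray(dosages, dtype=np.int16)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if dosages.shape[0] != len(individuals):
            raise ValueError("row count does not match number of individuals")
        if dosages.shape[1] != len(snps):
            raise ValueError("column count does not match SNP table")
        required = {"id", "chrom", "pos", "ref", "alt", "ancestral"}
        missing_cols = required - set(snps.columns)
        if missing_cols:
            raise ValueError(f"SNP table missing columns {sorted(missing_cols)}")
        if snps["id"].duplicated().any():
            raise ValueError("duplicate SNP ids in genotype matrix")
        self.dosages = dosages
        self.individuals = list(individuals)
        self.snps = snps.reset_index(drop=True)
        self._snp_index: Mapping[str, int] = {
            s: i for i, s in enumerate(self.snps["id"])
        }
        self._ind_index: Mapping[str, int] = {
            s: i for i, s in enumerate(self.individuals)
        }

    # -- basic shape -------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["id"])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenotypeMatrix({self.n_individuals} individuals x "
            f"{self.n_snps} SNPs)"
        )

    # -- indexing ----------------------------------------------------------
    def snp_indices(self, ids: Iterable[str]) -> np.ndarray:
        """Column indices of ``ids``; raises KeyError for absent SNPs."""
        return np.array([self._snp_index[i] for i in ids], dtype=np.intp)

    def individual_indices(self, ids: Iterable[str]) -> np.ndarray:
        return np.array([self._ind_index[i] for i in ids], dtype=np.intp)

    def individual_mask(self, ids: Iterable[str] | np.ndarray | None) -> np.ndarray:
        """Boolean row mask from an id list, an existing mask, or None (all)."""
        if ids is None:
            return np.ones(self.n_individuals, dtype=bool)
        arr = np.asarray(ids)
        if arr.dtype == bool:
            if arr.shape != (self.n_individuals,):
                raise ValueError("boolean mask has wrong length")
            return arr
        mask = np.zeros(self.n_individuals, dtype=bool)
        mask[self.individual_indices(arr)] = True
        return mask

    def dosage_of(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self._snp_index[snp_id]]

    # -- subsetting --------------------------------------------------------
    def subset_snps(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.snp_indices(ids)
        return GenotypeMatrix(
            self.dosages[:, idx], self.individuals, self.snps.iloc[idx]
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.individual_indices(ids)
        return GenotypeMatrix(
            self.dosages[idx, :], [self.individuals[i] for i in idx], self.snps
        )

    # -- derived views -----------------------------------------------------
    def derived_dosages(self) -> tuple[np.ndarray, np.ndarray]:
        """Derived-allele counts and a mask of SNPs with known ancestral state.

        Returns ``(counts, polarized)`` where ``counts`` has shape
        (n_individuals, n_snps) and equals the alt count where the ancestral
        allele is REF, ``2 - alt`` where it is ALT, and :data:`MISSING`
        wherever the call is missing; columns of unpolarized SNPs are
        :data:`MISSING` throughout and flagged False in ``polarized``.
        """
        anc = self.snps["ancestral"].to_numpy(dtype=object)
        ref = self.snps["ref"].to_numpy(dtype=object)
        alt = self.snps["alt"].to_numpy(dtype=object)
        anc_is_ref = np.array([a is not None and a == r for a, r in zip(anc, ref)])
        anc_is_alt = np.array([a is not None and a == t for a, t in zip(anc, alt)])
        polarized = anc_is_ref | anc_is_alt
        called = self.dosages != MISSING
        counts = np.full_like(self.dosages, MISSING)
        cols_ref = np.where(anc_is_ref)[0]
        cols_alt = np.where(anc_is_alt)[0]
        counts[:, cols_ref] = np.where(
            called[:, cols_ref], self.dosages[:, cols_ref], MISSING
        )
        counts[:, cols_alt] = np.where(
            called[:, cols_alt], 2 - self.dosages[:, cols_alt], MISSING
        )
        return counts, polarized

    def to_variant_records(self) -> list[VariantRecord]:
        records = []
        for j, row in self.snps.iterrows():
            records.append(
                VariantRecord(
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    id=str(row["id"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    ancestral=row["ancestral"] if pd.notna(row["ancestral"]) else None,
                    genotypes=self.dosages[:, j].copy(),
                )
            )
        return records

    @classmethod
    def from_variant_records(
        cls, records: Sequence[VariantRecord], individuals: Sequence[str]
    ) -> "GenotypeMatrix":
        if not records:
            raise ValueError("no variant records")
        snps = pd.DataFrame(
            {
                "id": [r.id for r in records],
                "chrom": [r.chrom for r in records],
                "pos": [r.pos for r in records],
                "ref": [r.ref for r in records],
                "alt": [r.alt for r in records],
                "ancestral": [r.ancestral for r in records],
            }
        )
        dosages = np.column_stack([r.genotypes for r in records]).astype(np.int16)
        return cls(dosages, individuals, snps)
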