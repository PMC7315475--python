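"""Unweighted polygenic risk scores and between-population differences.

The score for an individual over a trait SNP set is the normalized sum of
effect alleles,

    PRS = sum_i G_i / sum_i A_i,

with G_i in {0, 1, 2} the effect-allele count at SNP i and A_i the number
of called alleles at that SNP.  Hard diploid calls are assumed, so
A_i is 2 for a called genotype and 0 for a missing one (the haploid A_i = 1
case never arises from VCF hard calls).  Scores are deliberately not
weighted by effect sizes: associations curated from heterogeneous studies
do not have combinable effect estimates, and the comparison statistics
downstream only need allele counts.

Between-population differences (ΔPRS) are reported either on the
``count`` scale (difference of mean per-individual effect-allele counts;
the default used by the resampling corrections, whose printed magnitudes
are allele counts) or on the ``normalized`` [0, 1] scale.  The corrected
z-score downstream is invariant to this choice as long as the observed and
null values share a scale, which the pipeline enforces by recording the
scale on every ΔPRS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, SnpAssociation

logger = logging.getLogger("admixprs")


@dataclass
class MatchReport:
    """Accounting of association-to-genotype matching."""

    n_input: int
    matched: list[str]
    absent: list[str]
    allele_mismatch: list[str]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


@dataclass
class OrientedDosages:
    """Effect-allele dosages for the matched SNPs of an association set."""

    dosages: np.ndarray  # (n_individuals, n_matched), MISSING preserved
    snp_ids: list[str]
    individuals: list[str]
    report: MatchReport


@dataclass
class DeltaPrs:
    """Mean-per-individual PRS difference between two populations."""

    population_a: str
    population_b: str
    scale: str  # "count" | "normalized"
    value: float
    n_a: int
    n_b: int


def orient_dosages(
    matrix: GenotypeMatrix, associations: Sequence[SnpAssociation]
) -> OrientedDosages:
    """Convert alt-allele counts to effect-allele dosages per association.

    effect == ALT keeps the alt count; effect == REF flips to ``2 - alt``
    (missing stays missing); an effect allele matching neither is excluded
    and reported.  Raises if no association matches at all.
    """
    cols: list[int] = []
    flips: list[bool] = []
    matched: list[str] = []
    absent: list[str] = []
    mismatch: list[str] = []
    snp_lookup = {
        i: (j, r, t)
        for j, (i, r, t) in enumerate(
            zip(matrix.snps["id"], matrix.snps["ref"], matrix.snps["alt"])
        )
    }
    for a in associations:
        hit = snp_lookup.get(a.id)
        if hit is None:
            absent.append(a.id)
            continue
        j, ref, alt = hit
        if a.effect_allele == alt:
            cols.append(j)
            flips.append(False)
            matched.append(a.id)
        elif a.effect_allele == ref:
            cols.append(j)
            flips.append(True)
            matched.append(a.id)
        else:
            mismatch.append(a.id)
    report = MatchReport(
        n_input=len(associations),
        matched=matched,
        absent=absent,
        allele_mismatch=mismatch,
    )
    if not matched:
        raise ValueError(
            f"no association matched the genotypes "
            f"({len(absent)} absent, {len(mismatch)} allele mismatches)"
        )
    if absent or mismatch:
        logger.info(
            "orient_dosages: %d/%d matched (%d absent, %d allele mismatches)",
            len(matched),
            len(associations),
            len(absent),
            len(mismatch),
        )
    d = matrix.dosages[:, cols].astype(np.int16)
    flip = np.asarray(flips)
    called = d != MISSING
    d[:, flip] = np.where(called[:, flip], 2 - d[:, flip], MISSING)
    return OrientedDosages(
        dosages=d,
        snp_ids=matched,
        individuals=list(matrix.individuals),
        report=report,
    )


def compute_prs(oriented: OrientedDosages) -> pd.DataFrame:
    """Per-individual scores from oriented dosages.

    Returns a frame with columns individual_id, n_snps_used,
    effect_allele_count, called_allele_count, normalized_score,
    all_missing.  Individuals with every SNP missing get a NaN score and
    an ``all_missing`` flag; population summaries exclude them.
    """
    d = oriented.dosages
    called = d != MISSING
    eff = np.where(called, d, 0).sum(axis=1)
    called_alleles = 2 * called.sum(axis=1)
    all_missing = called_alleles == 0
    if all_missing.any():
        logger.warning(
            "compute_prs: %d individual(s) with all SNPs missing; "
            "flagged and excluded from population summaries",
            int(all_missing.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(all_missing, np.nan, eff / np.maximum(called_alleles, 1))
    return pd.DataFrame(
        {
            "individual_id": oriented.individuals,
            "n_snps_used": called.sum(axis=1),
            "effect_allele_count": eff,
            "called_allele_count": called_alleles,
            "normalized_score": score,
            "all_missing": all_missing,
        }
    )


def delta_prs(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    scale: str = "count",
    population_a: str = "A",
    population_b: str = "B",
) -> DeltaPrs:
    """Mean PRS difference A - B on the requested scale."""
    if scale not in ("count", "normalized"):
        raise ValueError(f"unknown scale {scale!r}")
    col = "effect_allele_count" if scale == "count" else "normalized_score"
    a = results_a.loc[~results_a["all_missing"], col].to_numpy(dtype=float)
    b = results_b.loc[~results_b["all_missing"], col].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty population after exclusions")
    return DeltaPrs(
        population_a=population_a,
        population_b=population_b,
        scale=scale,
        value=float(a.mean() - b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def per_snp_count_deltas(
    dosages: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray
) -> np.ndarray:
    """Per-SNP contribution to the count-scale ΔPRS(A, B).

    The count-scale ΔPRS of any SNP set is the sum of these per-SNP terms
    (mean effect-allele count in A minus in B, with missing calls
    contributing 0), an exact identity used by the null builders.
    """
    d = np.where(dosages == MISSING, 0, dosages).astype(float)
    return d[mask_a].mean(axis=0) - d[mask_b].mean(axis=0)


class PRSScorer:
    """Unweighted PRS as a transformer over genotype matrices.

    Parameters
    ----------
    associations
        The trait SNP set (effect alleles define the score).
    scale
        Score column returned by :meth:`transform`: ``"normalized"``
        (default, in [0, 1]) or ``"count"``.

    Attributes (after :meth:`fit`)
    ------------------------------
    snp_ids_ : matched SNP ids in scoring order.
    report_ : :class:`MatchReport` of the orientation step.
    """

    def __init__(
        self, associations: Sequence[SnpAssociation] | None = None, scale: str = "normalized"
    ) -> None:
        self.associations = associations
        self.scale = scale

    # sklearn-compatible parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {"associations": self.associations, "scale": self.scale}

    def set_params(self, **params) -> "PRSScorer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: GenotypeMatrix, y=None) -> "PRSScorer":
        if self.associations is None:
            raise ValueError("PRSScorer requires an association set")
        if self.scale not in ("count", "normalized"):
            raise ValueError(f"unknown scale {self.scale!r}")
        oriented = orient_dosages(X, self.associations)
        self.snp_ids_ = oriented.snp_ids
        self.report_ = oriented.report
        return self

    def score_frame(self, X: GenotypeMatrix) -> pd.DataFrame:
        """Full per-individual score table for ``X``."""
        if not hasattr(self, "snp_ids_"):
            raise ValueError("PRSScorer is not fitted")
        return compute_prs(orient_dosages(X, self.associations))

    def transform(self, X: GenotypeMatrix) -> np.ndarray:
        """Scores as a column vector (NaN for all-missing individuals)."""
        frame = self.score_frame(X)
        col = "effect_allele_count" if self.scale == "count" else "normalized_score"
        return frame[col].to_numpy(dtype=float).reshape(-1, 1)

    def fit_transform(self, X: GenotypeMatrix, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
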