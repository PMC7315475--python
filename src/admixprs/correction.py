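"""Derived-allele-frequency-matched resampling correction for ΔPRS.

Cross-population polygenic scores inherit two related distortions from
GWAS practice: genotyping arrays ascertain SNPs with high minor-allele
frequency in European populations, and discovery power likewise favors
them.  Because derived alleles are usually the minor alleles in discovery
cohorts, trait SNP sets end up with a derived-allele-frequency (DAF)
profile that is not exchangeable with arbitrary genome-wide SNPs, and
between-population DAF differences (driven by drift) then masquerade as
risk differences.

The control implemented here removes that bias in five steps:

1. Score both populations on the trait SNP set and form the observed
   between-population difference, obs ΔPRS (count scale).
2. Bin the trait SNPs' DAFs in the GWAS source population (bins of width
   0.05 on [0, 1], half-open with the last bin closed).
3. Draw random catalog SNP sets that reproduce that binned DAF profile
   bin-for-bin: for each trait SNP, one catalog SNP from the same
   source-population DAF bin (without replacement within a set, with
   replacement across sets).  Each sampled SNP's effect allele is set to
   its derived allele with probability equal to the trait set's
   derived-effect fraction, so the null inherits the trait set's
   ancestral/derived polarization mix rather than acquiring one.
4. Compute ΔPRS for every sampled set, yielding the null ΔPRS
   distribution (its between-population behavior enters through the
   sampled SNPs' own genotypes in the two populations compared).
5. Report the ancestry-corrected score

       corr.ΔPRS = (obs ΔPRS - mu_null) / sigma_null

   together with a one-tailed empirical P against the null samples.

The correction is conservative by construction: it absorbs any component
of the observed difference that arbitrary frequency-matched SNPs would
also show, and z is invariant to affine rescaling of the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from ._sampling import sample_index_sets
from .containers import MISSING, GenotypeMatrix, SnpAssociation
from .prs import DeltaPrs, orient_dosages
from .stats import NullDistribution, empirical_p

logger = logging.getLogger("admixprs")


# ---------------------------------------------------------------------------
# DAF tables and distributions
# ---------------------------------------------------------------------------


@dataclass
class DafTable:
    """Per-SNP derived-allele frequencies in named populations.

    Only SNPs with a known ancestral state are included.  ``frequencies``
    is indexed by SNP id with one column per population;
    ``derived_allele`` gives the derived base per SNP.
    """

    frequencies: pd.DataFrame
    derived_allele: pd.Series
    ancestral_allele: pd.Series
    polarization_source: str
    n_excluded_unpolarized: int
    n_excluded_uncalled: int

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.frequencies.index

    def daf(self, population: str) -> pd.Series:
        return self.frequencies[population]


def compute_daf(
    matrix: GenotypeMatrix,
    populations: Mapping[str, object],
    polarization_source: str = "AA",
) -> DafTable:
    """Derived-allele frequency per SNP in each named population.

    ``populations`` maps a name to an individual-id list or boolean row
    mask.  DAF is the frequency of the non-ancestral allele among called
    alleles.  SNPs with unknown ancestral state are excluded and counted;
    SNPs with zero called alleles in any named population are excluded
    with a warning.
    """
    derived, polarized = matrix.derived_dosages()
    masks = {name: matrix.individual_mask(sel) for name, sel in populations.items()}
    called = derived != MISSING
    counts = np.where(called, derived, 0)
    freq_cols: dict[str, np.ndarray] = {}
    any_uncalled = np.zeros(matrix.n_snps, dtype=bool)
    for name, mask in masks.items():
        n_alleles = 2 * called[mask].sum(axis=0)
        any_uncalled |= n_alleles == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            freq_cols[name] = np.where(
                n_alleles > 0, counts[mask].sum(axis=0) / np.maximum(n_alleles, 1), np.nan
            )
    keep = polarized & ~any_uncalled
    n_unpolarized = int((~polarized).sum())
    n_uncalled = int((polarized & any_uncalled).sum())
    if n_uncalled:
        logger.warning(
            "compute_daf: excluded %d SNP(s) with zero called alleles in a population",
            n_uncalled,
        )
    ids = matrix.snps["id"].to_numpy()[keep]
    frequencies = pd.DataFrame(
        {name: col[keep] for name, col in freq_cols.items()}, index=pd.Index(ids, name="id")
    )
    anc = matrix.snps["ancestral"].to_numpy(dtype=object)[keep]
    ref = matrix.snps["ref"].to_numpy(dtype=object)[keep]
    alt = matrix.snps["alt"].to_numpy(dtype=object)[keep]
    derived_base = np.where(anc == ref, alt, ref)
    return DafTable(
        frequencies=frequencies,
        derived_allele=pd.Series(derived_base, index=frequencies.index),
        ancestral_allele=pd.Series(anc.astype(str), index=frequencies.index),
        polarization_source=polarization_source,
        n_excluded_unpolarized=n_unpolarized,
        n_excluded_uncalled=n_uncalled,
    )


@dataclass
class DafDistribution:
    """Binned DAF histogram of a trait SNP set in the source population.

    Bins are half-open [a, b) on [0, 1] with the final bin closed; counts
    sum to the number of polarized trait SNPs binned.
    """

    edges: np.ndarray
    counts: np.ndarray
    source_population: str
    bin_width: float

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def n_snps(self) -> int:
        return int(self.counts.sum())

    def bin_of(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value under the half-open convention."""
        v = np.asarray(values, dtype=float)
        idx = np.digitize(v, self.edges) - 1
        return np.clip(idx, 0, self.n_bins - 1)


def _bin_edges(bin_width: float) -> np.ndarray:
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not tile [0, 1] exactly")
    return np.linspace(0.0, 1.0, n_bins + 1)


def trait_daf_distribution(
    daf_table: DafTable,
    trait_ids: Sequence[str],
    source_population: str,
    bin_width: float = 0.05,
) -> DafDistribution:
    """Histogram of trait-SNP DAFs in the GWAS source population."""
    present = [i for i in trait_ids if i in daf_table.frequencies.index]
    if not present:
        raise ValueError("no trait SNP present in the DAF table")
    edges = _bin_edges(bin_width)
    dist = DafDistribution(
        edges=edges,
        counts=np.zeros(edges.size - 1, dtype=int),
        source_population=source_population,
        bin_width=bin_width,
    )
    values = daf_table.frequencies.loc[present, source_population].to_numpy()
    idx = dist.bin_of(values)
    np.add.at(dist.counts, idx, 1)
    return dist


# ---------------------------------------------------------------------------
# matched resampling
# ---------------------------------------------------------------------------


def _catalog_bins(
    daf_table: DafTable, catalog_ids: Sequence[str], dist: DafDistribution
) -> tuple[list[str], np.ndarray]:
    ids = [i for i in catalog_ids if i in daf_table.frequencies.index]
    if not ids:
        raise ValueError("no catalog SNP present in the DAF table")
    values = daf_table.frequencies.loc[ids, dist.source_population].to_numpy()
    return ids, dist.bin_of(values)


def _check_bin_occupancy(
    dist: DafDistribution, bin_assign: np.ndarray
) -> dict[int, np.ndarray]:
    pools: dict[int, np.ndarray] = {}
    for b in np.nonzero(dist.counts)[0]:
        pool = np.where(bin_assign == b)[0]
        need = int(dist.counts[b])
        if pool.size < need:
            lo, hi = dist.edges[b], dist.edges[b + 1]
            raise ValueError(
                f"DAF bin [{lo:.2f}, {hi:.2f}) holds {pool.size} catalog SNP(s) "
                f"but the trait set needs {need}; supply a larger catalog or "
                f"wider bins"
            )
        pools[int(b)] = pool
    return pools


def daf_matched_sample(
    catalog_ids: Sequence[str],
    trait_dist: DafDistribution,
    daf_table: DafTable,
    derived_effect_fraction: float,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw one DAF-matched SNP set with assigned effect alleles.

    For each trait SNP, one catalog SNP is drawn uniformly without
    replacement from the same source-population DAF bin; its effect allele
    is the derived allele with probability ``derived_effect_fraction``,
    else the ancestral allele.  Returns a frame with columns id,
    effect_is_derived, effect_allele.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ids, bin_assign = _catalog_bins(daf_table, catalog_ids, trait_dist)
    pools = _check_bin_occupancy(trait_dist, bin_assign)
    picked: list[int] = []
    for b in sorted(pools):
        pool = pools[b]
        take = rng.choice(pool, size=int(trait_dist.counts[b]), replace=False)
        picked.extend(int(t) for t in take)
    picked_ids = [ids[i] for i in picked]
    is_derived = rng.random(len(picked)) < derived_effect_fraction
    derived = daf_table.derived_allele.loc[picked_ids].to_numpy()
    ancestral = daf_table.ancestral_allele.loc[picked_ids].to_numpy()
    return pd.DataFrame(
        {
            "id": picked_ids,
            "effect_is_derived": is_derived,
            "effect_allele": np.where(is_derived, derived, ancestral),
            "other_allele": np.where(is_derived, ancestral, derived),
        }
    )


def _per_snp_polarized_deltas(
    matrix: GenotypeMatrix,
    snp_ids: Sequence[str],
    mask_a: np.ndarray,
    mask_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Count-scale per-SNP ΔPRS terms for derived- and ancestral-effect alleles.

    For a SNP whose effect allele is the derived one, the per-SNP term is
    the between-cohort difference in mean derived-allele count (missing
    contributing 0); for an ancestral effect allele the per-individual
    count is ``called*2 - derived``, so the term follows from the called
    fraction and the derived term.
    """
    sub = matrix.subset_snps(list(snp_ids))
    derived, polarized = sub.derived_dosages()
    if not polarized.all():
        raise ValueError("unpolarized SNP passed to the matched-null builder")
    called = derived != MISSING
    cnt = np.where(called, derived, 0).astype(float)
    mean_der_a = cnt[mask_a].mean(axis=0)
    mean_der_b = cnt[mask_b].mean(axis=0)
    called2_a = 2.0 * called[mask_a].mean(axis=0)
    called2_b = 2.0 * called[mask_b].mean(axis=0)
    delta_derived = mean_der_a - mean_der_b
    delta_ancestral = (called2_a - mean_der_a) - (called2_b - mean_der_b)
    return delta_derived, delta_ancestral


def daf_matched_null(
    matrix: GenotypeMatrix,
    catalog_ids: Sequence[str],
    trait_dist: DafDistribution,
    daf_table: DafTable,
    pop_a,
    pop_b,
    derived_effect_fraction: float,
    n_draws: int = 500_000,
    seed: int | None = None,
) -> NullDistribution:
    """Null ΔPRS distribution from DAF-matched random SNP sets.

    Implements the matched-sampling protocol of :func:`daf_matched_sample`
    in bulk: sets are drawn bin-by-bin without replacement within a set,
    effect-allele polarization is Bernoulli(``derived_effect_fraction``)
    per sampled SNP, and each set's count-scale ΔPRS is the sum of the
    corresponding per-SNP terms.
    """
    rng = np.random.default_rng(seed)
    ids, bin_assign = _catalog_bins(daf_table, catalog_ids, trait_dist)
    pools = _check_bin_occupancy(trait_dist, bin_assign)
    mask_a = matrix.individual_mask(pop_a)
    mask_b = matrix.individual_mask(pop_b)
    delta_der, delta_anc = _per_snp_polarized_deltas(matrix, ids, mask_a, mask_b)
    samples = np.zeros(n_draws)
    for b in sorted(pools):
        pool = pools[b]
        need = int(trait_dist.counts[b])
        sets = sample_index_sets(rng, pool.size, need, n_draws)
        idx = pool[sets]  # (n_draws, need) catalog indices
        pol = rng.random(idx.shape) < derived_effect_fraction
        samples += np.where(pol, delta_der[idx], delta_anc[idx]).sum(axis=1)
    return NullDistribution.from_samples(samples, seed, "daf_matched")


# ---------------------------------------------------------------------------
# the corrected score
# ---------------------------------------------------------------------------


@dataclass
class CorrectionResult:
    """Observed ΔPRS against its matched null, as a z-score."""

    obs_delta_prs: float
    null_mean: float
    null_sd: float
    corrected_z: float
    empirical_p: float
    p_normal: float  # normal-theory tail of z; secondary to the empirical P
    n_draws: int
    seed: int | None
    alternative: str
    scale: str = "count"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "obs_delta_prs": self.obs_delta_prs,
                    "null_mean": self.null_mean,
                    "null_sd": self.null_sd,
                    "corrected_z": self.corrected_z,
                    "empirical_p": self.empirical_p,
                    "p_normal": self.p_normal,
                    "n_draws": self.n_draws,
                    "seed": self.seed,
                }
            ]
        )


def corrected_z_score(obs_delta: float, null_mean: float, null_sd: float) -> float:
    """The correction formula: (obs ΔPRS - mu_null) / sigma_null."""
    if null_sd <= 0:
        raise ValueError("null standard deviation must be positive")
    return (obs_delta - null_mean) / null_sd


def corrected_delta_prs(
    obs_delta: float | DeltaPrs,
    null: NullDistribution,
    alternative: str = "observed",
) -> CorrectionResult:
    """Compare the observed ΔPRS to a resampled null; return the z and P.

    ``obs_delta`` may be a :class:`~admixprs.prs.DeltaPrs` (its scale must
    match the null's) or a bare value already on the null's scale.
    """
    if isinstance(obs_delta, DeltaPrs):
        if obs_delta.scale != null.scale:
            raise ValueError(
                f"observed ΔPRS scale {obs_delta.scale!r} does not match "
                f"null scale {null.scale!r}"
            )
        obs = obs_delta.value
    else:
        obs = float(obs_delta)
    z = corrected_z_score(obs, null.mean, null.sd)
    p_emp = empirical_p(obs, null, alternative=alternative)
    direction = alternative
    if direction == "observed":
        direction = "greater" if obs >= null.mean else "less"
    p_norm = float(sp_stats.norm.sf(z) if direction == "greater" else sp_stats.norm.cdf(z))
    return CorrectionResult(
        obs_delta_prs=obs,
        null_mean=null.mean,
        null_sd=null.sd,
        corrected_z=z,
        empirical_p=p_emp,
        p_normal=p_norm,
        n_draws=null.n_draws,
        seed=null.seed,
        alternative=alternative,
        scale=null.scale,
    )


class DafCorrection:
    """The full five-step ancestry-bias control as a fit-style estimator.

    Parameters
    ----------
    bin_width
        DAF histogram bin width (default 0.05, i.e. 20 bins).
    n_draws
        Matched null sets to draw (the study default is 500,000; smaller
        values trade empirical-P resolution for speed).
    derived_effect_fraction
        Ancestral/derived mix imposed on sampled effect alleles; None
        (default) mirrors the trait set's own fraction.
    alternative
        Tail for the empirical P: "greater", "less", or "observed".
    random_state
        Seed for the matched resampling.

    After ``fit``: ``observed_delta_``, ``null_``, ``corrected_z_``,
    ``empirical_p_``, ``result_``, ``derived_effect_fraction_``,
    ``n_trait_snps_``.
    """

    def __init__(
        self,
        bin_width: float = 0.05,
        n_draws: int = 500_000,
        derived_effect_fraction: float | None = None,
        alternative: str = "observed",
        random_state: int | None = None,
    ) -> None:
        self.bin_width = bin_width
        self.n_draws = n_draws
        self.derived_effect_fraction = derived_effect_fraction
        self.alternative = alternative
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "bin_width": self.bin_width,
            "n_draws": self.n_draws,
            "derived_effect_fraction": self.derived_effect_fraction,
            "alternative": self.alternative,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "DafCorrection":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        X: GenotypeMatrix,
        y=None,
        *,
        associations: Sequence[SnpAssociation],
        catalog_ids: Sequence[str],
        pop_a,
        pop_b,
        source_pop,
    ) -> "DafCorrection":
        """Run steps 1-5 on genotypes ``X``.

        ``pop_a``/``pop_b`` are the populations compared (id lists or row
        masks); ``source_pop`` the GWAS discovery source population whose
        DAFs parameterize the matching; ``catalog_ids`` the genome-wide
        SNP pool resampled from (trait SNPs are excluded automatically).
        """
        mask_a = X.individual_mask(pop_a)
        mask_b = X.individual_mask(pop_b)
        daf = compute_daf(X, {"pop_a": mask_a, "pop_b": mask_b, "source": source_pop})

        # Step 1: observed ΔPRS over the polarized, matched trait SNPs.
        oriented = orient_dosages(X, associations)
        trait_ids = [i for i in oriented.snp_ids if i in daf]
        if not trait_ids:
            raise ValueError("no polarized trait SNP available for the correction")
        trait_cols = [oriented.snp_ids.index(i) for i in trait_ids]
        from .prs import per_snp_count_deltas

        obs = float(
            per_snp_count_deltas(
                oriented.dosages[:, trait_cols], mask_a, mask_b
            ).sum()
        )

        # Trait polarization mix (derived-effect fraction).
        eff_by_id = {a.id: a.effect_allele for a in associations}
        derived = daf.derived_allele.loc[trait_ids]
        frac = float(
            np.mean([eff_by_id[i] == derived.loc[i] for i in trait_ids])
        )
        if self.derived_effect_fraction is not None:
            frac = self.derived_effect_fraction

        # Steps 2-4: matched null.
        dist = trait_daf_distribution(daf, trait_ids, "source", self.bin_width)
        trait_set = set(trait_ids)
        pool = [i for i in catalog_ids if i not in trait_set]
        null = daf_matched_null(
            X,
            pool,
            dist,
            daf,
            mask_a,
            mask_b,
            derived_effect_fraction=frac,
            n_draws=self.n_draws,
            seed=self.random_state,
        )

        # Step 5: the corrected score.
        self.result_ = corrected_delta_prs(obs, null, alternative=self.alternative)
        self.observed_delta_ = obs
        self.null_ = null
        self.corrected_z_ = self.result_.corrected_z
        self.empirical_p_ = self.result_.empirical_p
        self.derived_effect_fraction_ = frac
        self.n_trait_snps_ = len(trait_ids)
        self.daf_table_ = daf
        self.trait_distribution_ = dist
        return self
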