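"""Synthetic admixed-cohort generator with a known risk architecture.

Every downstream stage of the pipeline is exercised on cohorts produced
here, so the generator is first-class, deterministic code rather than a
test fixture.  It emulates the structure of the real study inputs:

* **Three-way admixture.**  Each individual's ancestry vector over the
  ancestral populations AFR / EUR / NAT is drawn from a cohort-specific
  Dirichlet.  The two default cohorts mirror the contrast between an
  African-enriched admixed population (mean 0.76/0.13/0.11) and a
  European-enriched one (mean 0.07/0.75/0.18).
* **Population-differentiated allele frequencies.**  A global derived-allele
  frequency ``p`` is drawn per SNP from Uniform(0.05, 0.95); each ancestral
  population's derived-allele frequency is then Balding–Nichols:
  Beta with mean ``p`` and variance ``F * p * (1 - p)``, i.e. shape
  parameters ``p (1-F)/F`` and ``(1-p)(1-F)/F``.  Default ``F = 0.15`` per
  population, a conventional continental-scale differentiation magnitude.
* **Ancestral/derived polarization.**  The ancestral state is simulated
  explicitly (and written to the AA tag), so the derived-allele frequency
  is exactly known in tests.  Which of REF/ALT is ancestral is random per
  SNP, exercising allele orientation downstream.
* **An embedded risk architecture.**  ``n_risk_snps`` SNPs become trait
  associations.  Each effect allele is the derived allele with probability
  ``derived_effect_fraction`` (default 0.56, the ancestral/derived mix
  reported for curated GWAS risk alleles).  The effect-allele frequency is
  shifted by +delta/2 in one target ancestral population and -delta/2 in
  the other, clipped to [0.01, 0.99], creating a known true
  between-population score differential (expected count-scale mean
  difference 2 * n_risk * delta between unadmixed target populations).
* **Ascertainment-bias emulation.**  With ``ascertainment_bias > 0`` risk
  SNPs are drawn with probability proportional to
  ``DAF_source ** ascertainment_bias`` instead of uniformly, enriching the
  trait set for high derived-allele frequency in the GWAS source
  population — the distortion the frequency-matched correction removes.

All randomness flows from ``config.seed`` through a ``SeedSequence`` spawn
tree (frequencies, risk embedding, catalog polarity, then one child per
cohort), so stages are individually re-runnable and the whole simulation is
bit-reproducible.  SNPs are statistically independent: linkage
disequilibrium is deliberately not simulated (pruning tests build
correlated columns explicitly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, AncestryProfile, GenotypeMatrix, SnpAssociation

logger = logging.getLogger("admixprs")

#: Ancestral population order used throughout the simulator.
POPULATIONS = ("AFR", "EUR", "NAT")

_COMPONENT_OF = {"AFR": "f_African", "EUR": "f_European", "NAT": "f_NativeAmerican"}

_DEFAULT_COHORTS: dict[str, tuple[float, float, float]] = {
    # Dirichlet concentrations = mean * 30; means follow the observed
    # ancestry contrast between an African-enriched and a European-enriched
    # admixed American population.
    "african_admixed": (22.8, 3.9, 3.3),
    "european_admixed": (2.1, 22.5, 5.4),
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    ``cohorts`` maps cohort label to a Dirichlet concentration vector over
    (AFR, EUR, NAT).  ``risk_daf_shift`` is the between-population
    effect-allele frequency difference delta embedded at risk SNPs
    (+delta/2 / -delta/2 in the two ``shift_populations``).
    """

    n_snps: int = 20_000
    n_individuals: int = 100
    cohorts: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COHORTS)
    )
    fst: Mapping[str, float] = field(
        default_factory=lambda: {"AFR": 0.15, "EUR": 0.15, "NAT": 0.15}
    )
    n_risk_snps: int = 100
    risk_daf_shift: float = 0.0
    derived_effect_fraction: float = 0.56
    shift_populations: tuple[str, str] = ("AFR", "EUR")
    source_population: str = "EUR"
    ascertainment_bias: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0 or self.n_individuals <= 0 or self.n_risk_snps <= 0:
            raise ValueError("counts must be positive")
        if self.n_risk_snps > self.n_snps:
            raise ValueError("n_risk_snps exceeds n_snps")
        if not -1.0 <= self.risk_daf_shift <= 1.0:
            raise ValueError("risk_daf_shift outside [-1, 1]")
        if not 0.0 <= self.derived_effect_fraction <= 1.0:
            raise ValueError("derived_effect_fraction outside [0, 1]")
        for k, f in self.fst.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"F for {k} outside (0, 1)")
        for pop in self.shift_populations:
            if pop not in POPULATIONS:
                raise ValueError(f"unknown shift population {pop!r}")
        if self.source_population not in POPULATIONS:
            raise ValueError(f"unknown source population {self.source_population!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate outside [0, 1)")


@dataclass
class AncestralFrequencyTable:
    """Per-SNP allele metadata and per-population derived-allele frequencies.

    ``p`` is the global derived-allele frequency; ``q[pop]`` the
    Balding–Nichols frequency in each ancestral population.  ``snps`` holds
    id/chrom/pos/ref/alt/ancestral with the simulated polarization.
    """

    snps: pd.DataFrame
    p: np.ndarray
    q: dict[str, np.ndarray]
    fst: Mapping[str, float]

    def __len__(self) -> int:
        return len(self.p)

    @property
    def derived_allele(self) -> np.ndarray:
        """Derived base per SNP (the non-ancestral one of ref/alt)."""
        anc_is_ref = self.snps["ancestral"].to_numpy() == self.snps["ref"].to_numpy()
        return np.where(anc_is_ref, self.snps["alt"], self.snps["ref"])

    def copy(self) -> "AncestralFrequencyTable":
        return AncestralFrequencyTable(
            snps=self.snps.copy(),
            p=self.p.copy(),
            q={k: v.copy() for k, v in self.q.items()},
            fst=dict(self.fst),
        )


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


_ALLELE_PAIRS = np.array([("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")])


def simulate_frequencies(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> AncestralFrequencyTable:
    """Draw global and per-population derived-allele frequencies.

    In the ``F -> 0`` limit the Beta concentrates at ``p``; empirically the
    variance of ``q - p`` equals ``F * E[p(1-p)]``.
    """
    rng = _rng(rng if rng is not None else config.seed)
    n = config.n_snps
    p = rng.uniform(0.05, 0.95, size=n)
    q: dict[str, np.ndarray] = {}
    for pop in POPULATIONS:
        f = config.fst[pop]
        a = p * (1.0 - f) / f
        b = (1.0 - p) * (1.0 - f) / f
        q[pop] = np.clip(rng.beta(a, b), 0.0, 1.0)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ref = _ALLELE_PAIRS[pair_idx, 0]
    alt = _ALLELE_PAIRS[pair_idx, 1]
    anc_is_ref = rng.random(n) < 0.5
    ancestral = np.where(anc_is_ref, ref, alt)
    snps = pd.DataFrame(
        {
            "id": [f"snp{i:06d}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(1, n + 1) * 1000,
            "ref": ref,
            "alt": alt,
            "ancestral": ancestral,
        }
    )
    return AncestralFrequencyTable(snps=snps, p=p, q=q, fst=dict(config.fst))


def embed_risk_architecture(
    freqs: AncestralFrequencyTable,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[SnpAssociation], AncestralFrequencyTable, np.ndarray]:
    """Select risk SNPs, polarize effect alleles, and shift their frequencies.

    Returns the association list (effect/other alleles oriented to the
    simulated ref/alt), a modified frequency table, and the risk SNP
    indices.  Frequency shifts that leave [0.01, 0.99] are clipped with a
    logged count.
    """
    rng = _rng(rng if rng is not None else config.seed)
    n = len(freqs)
    if config.n_risk_snps > n:
        raise ValueError("n_risk_snps exceeds table length")
    if config.ascertainment_bias > 0.0:
        w = freqs.q[config.source_population] ** config.ascertainment_bias
        w = w / w.sum()
        risk_idx = rng.choice(n, size=config.n_risk_snps, replace=False, p=w)
    else:
        risk_idx = rng.choice(n, size=config.n_risk_snps, replace=False)
    risk_idx = np.sort(risk_idx)
    effect_is_derived = rng.random(config.n_risk_snps) < config.derived_effect_fraction

    out = freqs.copy()
    delta = config.risk_daf_shift
    n_clipped = 0
    if delta != 0.0:
        pop_up, pop_down = config.shift_populations
        # shift on the effect-allele scale; translate to the derived scale
        sign = np.where(effect_is_derived, 1.0, -1.0)
        for pop, direction in ((pop_up, +0.5), (pop_down, -0.5)):
            shifted = out.q[pop][risk_idx] + sign * direction * delta
            clipped = np.clip(shifted, 0.01, 0.99)
            n_clipped += int(np.sum(clipped != shifted))
            out.q[pop][risk_idx] = clipped
        if n_clipped:
            logger.info("embed_risk_architecture: clipped %d shifted frequencies", n_clipped)

    derived = freqs.derived_allele
    ancestral = freqs.snps["ancestral"].to_numpy()
    associations = []
    for k, i in enumerate(risk_idx):
        if effect_is_derived[k]:
            eff, oth, polarity = derived[i], ancestral[i], "derived"
        else:
            eff, oth, polarity = ancestral[i], derived[i], "ancestral"
        row = freqs.snps.iloc[i]
        associations.append(
            SnpAssociation(
                id=row["id"],
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                effect_allele=str(eff),
                other_allele=str(oth),
                cohort_ancestry=frozenset({"European"}),
                effect_polarity=polarity,
            )
        )
    return associations, out, risk_idx


def simulate_cohort(
    freqs: AncestralFrequencyTable,
    config: SimulationConfig,
    cohort: str,
    rng: np.random.Generator | int | None = None,
) -> tuple[GenotypeMatrix, list[AncestryProfile]]:
    """Simulate one admixed cohort under the frequency table.

    Each individual's ancestry vector is Dirichlet; each of the two allele
    copies at a SNP independently picks an ancestral population by those
    proportions and is derived with that population's frequency, so the
    derived count is Binomial(2, sum_k f_k q_k).  Genotypes are stored as
    alternate-allele counts with the simulated AA annotation.
    """
    rng = _rng(rng if rng is not None else config.seed)
    alpha = np.asarray(config.cohorts[cohort], dtype=float)
    n_ind = config.n_individuals
    fractions = rng.dirichlet(alpha, size=n_ind)  # (n_ind, 3) in POPULATIONS order
    qmat = np.vstack([freqs.q[pop] for pop in POPULATIONS])  # (3, n_snps)
    pi = fractions @ qmat  # derived-allele probability per individual x SNP
    derived_counts = rng.binomial(2, pi).astype(np.int16)
    anc_is_ref = (
        freqs.snps["ancestral"].to_numpy() == freqs.snps["ref"].to_numpy()
    )
    dosages = np.where(anc_is_ref[None, :], derived_counts, 2 - derived_counts)
    if config.missing_rate > 0.0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages = np.where(miss, MISSING, dosages)
    ids = [f"{cohort}_{i:04d}" for i in range(n_ind)]
    matrix = GenotypeMatrix(dosages.astype(np.int16), ids, freqs.snps)
    profiles = [
        AncestryProfile(ids[i], *(fractions[i] / fractions[i].sum()))
        for i in range(n_ind)
    ]
    return matrix, profiles


@dataclass
class Study:
    """One complete synthetic study: genotypes, truth, and trait/catalog tables."""

    genotypes: GenotypeMatrix
    cohort_masks: dict[str, np.ndarray]
    ancestry: list[AncestryProfile]
    associations: list[SnpAssociation]
    catalog: pd.DataFrame  # id, effect_allele, other_allele, effect_polarity
    freqs: AncestralFrequencyTable
    risk_ids: list[str]
    config: SimulationConfig


def generate_study(config: SimulationConfig) -> Study:
    """Run the full generator: frequencies, risk embedding, cohorts, catalog.

    The catalog pool is every non-risk SNP, each assigned its own effect
    allele (derived with probability ``derived_effect_fraction``), standing
    in for a genome-wide set of trait-associated SNPs to resample from.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(3 + len(config.cohorts))
    rng_freq, rng_embed, rng_catalog = (np.random.default_rng(c) for c in children[:3])

    freqs = simulate_frequencies(config, rng_freq)
    associations, freqs, risk_idx = embed_risk_architecture(freqs, config, rng_embed)

    matrices = []
    profiles: list[AncestryProfile] = []
    masks: dict[str, np.ndarray] = {}
    offset = 0
    n_total = config.n_individuals * len(config.cohorts)
    for cohort, child in zip(config.cohorts, children[3:]):
        m, prof = simulate_cohort(freqs, config, cohort, np.random.default_rng(child))
        matrices.append(m)
        profiles.extend(prof)
        mask = np.zeros(n_total, dtype=bool)
        mask[offset : offset + m.n_individuals] = True
        masks[cohort] = mask
        offset += m.n_individuals
    genotypes = GenotypeMatrix(
        np.vstack([m.dosages for m in matrices]),
        [i for m in matrices for i in m.individuals],
        freqs.snps,
    )

    risk_set = set(risk_idx.tolist())
    cat_idx = np.array([i for i in range(len(freqs)) if i not in risk_set])
    cat_derived = rng_catalog.random(len(cat_idx)) < config.derived_effect_fraction
    derived = freqs.derived_allele
    ancestral = freqs.snps["ancestral"].to_numpy()
    catalog = pd.DataFrame(
        {
            "id": freqs.snps["id"].to_numpy()[cat_idx],
            "chrom": freqs.snps["chrom"].to_numpy()[cat_idx],
            "pos": freqs.snps["pos"].to_numpy()[cat_idx],
            "effect_allele": np.where(
                cat_derived, derived[cat_idx], ancestral[cat_idx]
            ),
            "other_allele": np.where(
                cat_derived, ancestral[cat_idx], derived[cat_idx]
            ),
            "effect_polarity": np.where(cat_derived, "derived", "ancestral"),
        }
    )
    return Study(
        genotypes=genotypes,
        cohort_masks=masks,
        ancestry=profiles,
        associations=associations,
        catalog=catalog,
        freqs=freqs,
        risk_ids=[freqs.snps["id"].iloc[i] for i in risk_idx],
        config=config,
    )
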