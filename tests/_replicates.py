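"""Replicated synthetic-study pipelines shared by calibration/power tests.

Each replicate generates a fresh study, scores it, and runs the matched
(and optionally unmatched) null, returning summary statistics.  Session
fixtures in conftest run the batches once and several tests consume them.
"""

from __future__ import annotations

import numpy as np

from admixprs import (
    DafCorrection,
    SimulationConfig,
    SnpAssociation,
    empirical_p,
    fit_ols,
    generate_study,
    permutation_null,
)
from admixprs.io import ancestry_frame
from admixprs.prs import compute_prs, orient_dosages


def catalog_associations(catalog) -> list[SnpAssociation]:
    return [
        SnpAssociation(
            id=str(i), chrom=str(c), pos=int(p), effect_allele=str(e), other_allele=str(o)
        )
        for i, c, p, e, o in zip(
            catalog["id"],
            catalog["chrom"],
            catalog["pos"],
            catalog["effect_allele"],
            catalog["other_allele"],
        )
    ]


def run_replicate(
    seed: int,
    delta: float = 0.0,
    ascertainment: float = 0.0,
    n_snps: int = 20_000,
    n_draws: int = 5_000,
    identical_cohorts: bool = False,
    with_permutation: bool = False,
    with_ols: bool = False,
) -> dict:
    """One full pipeline run; cohort A is the African-enriched one."""
    kwargs: dict = dict(
        n_snps=n_snps,
        n_individuals=100,
        n_risk_snps=100,
        risk_daf_shift=delta,
        ascertainment_bias=ascertainment,
        seed=seed,
    )
    if identical_cohorts:
        alpha = (22.8, 3.9, 3.3)
        kwargs["cohorts"] = {"cohort_a": alpha, "cohort_b": alpha}
    config = SimulationConfig(**kwargs)
    study = generate_study(config)
    names = list(config.cohorts)
    mask_a, mask_b = study.cohort_masks[names[0]], study.cohort_masks[names[1]]

    model = DafCorrection(
        n_draws=n_draws, random_state=seed + 1, alternative="greater"
    ).fit(
        study.genotypes,
        associations=study.associations,
        catalog_ids=study.catalog["id"].tolist(),
        pop_a=mask_a,
        pop_b=mask_b,
        source_pop=mask_b,  # European-enriched cohort as GWAS source proxy
    )
    out = {
        "obs_delta": model.observed_delta_,
        "null_mean": model.null_.mean,
        "null_sd": model.null_.sd,
        "corrected_z": model.corrected_z_,
        "corrected_p": model.empirical_p_,
    }
    if with_permutation:
        null = permutation_null(
            study.genotypes,
            catalog_associations(study.catalog),
            set_size=len(study.associations),
            pop_a=mask_a,
            pop_b=mask_b,
            n_draws=n_draws,
            seed=seed + 2,
        )
        out["perm_mean"] = null.mean
        out["perm_sd"] = null.sd
        out["perm_p"] = empirical_p(model.observed_delta_, null, alternative="greater")
    if with_ols:
        oriented = orient_dosages(study.genotypes, study.associations)
        scores = compute_prs(oriented)
        profiles = ancestry_frame(study.ancestry)
        fit = fit_ols(
            scores["normalized_score"].to_numpy(),
            profiles.loc[scores["individual_id"], "f_African"].to_numpy(),
        )
        out["beta_african"] = fit.beta
    return out


def run_scored_delta_replicate(seed: int) -> dict:
    """Tiny delta=0, identical-ancestry replicate: observed count-scale ΔPRS
    and its binomial standard error from within-cohort dosage variances."""
    alpha = (22.8, 3.9, 3.3)
    config = SimulationConfig(
        n_snps=150,
        n_individuals=100,
        n_risk_snps=100,
        risk_daf_shift=0.0,
        cohorts={"cohort_a": alpha, "cohort_b": alpha},
        seed=seed,
    )
    study = generate_study(config)
    mask_a = study.cohort_masks["cohort_a"]
    mask_b = study.cohort_masks["cohort_b"]
    oriented = orient_dosages(study.genotypes, study.associations)
    d = oriented.dosages.astype(float)
    a, b = d[mask_a], d[mask_b]
    obs = a.sum(axis=1).mean() - b.sum(axis=1).mean()
    se = float(
        np.sqrt(
            (a.var(axis=0, ddof=1) / a.shape[0]).sum()
            + (b.var(axis=0, ddof=1) / b.shape[0]).sum()
        )
    )
    return {"obs_delta": float(obs), "se": se}
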