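from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from admixprs import GenotypeMatrix, SimulationConfig, generate_study

from _replicates import run_replicate, run_scored_delta_replicate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(dosages, ancestral=None, positions=None, chrom="1") -> GenotypeMatrix:
    """Small hand-built genotype matrix; columns are SNPs s0, s1, ..."""
    dosages = np.asarray(dosages, dtype=np.int16)
    n_ind, n_snp = dosages.shape
    if positions is None:
        positions = [(j + 1) * 100 for j in range(n_snp)]
    if ancestral is None:
        ancestral = [None] * n_snp
    snps = pd.DataFrame(
        {
            "id": [f"s{j}" for j in range(n_snp)],
            "chrom": chrom,
            "pos": positions,
            "ref": ["A"] * n_snp,
            "alt": ["G"] * n_snp,
            "ancestral": ancestral,
        }
    )
    return GenotypeMatrix(dosages, [f"ind{i}" for i in range(n_ind)], snps)


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study with an embedded differential."""
    config = SimulationConfig(
        n_snps=2_000, n_individuals=60, n_risk_snps=60, risk_daf_shift=0.1, seed=42
    )
    return generate_study(config)


@pytest.fixture(scope="session")
def null_batch():
    """200 delta=0 pipelines at full study scale (calibration)."""
    return [
        run_replicate(10_000 + i, delta=0.0, with_permutation=True)
        for i in range(200)
    ]


@pytest.fixture(scope="session")
def bias_batch():
    """200 delta=0 pipelines with ascertainment-bias emulation."""
    return [
        run_replicate(20_000 + i, delta=0.0, ascertainment=2.0, with_permutation=True)
        for i in range(200)
    ]


@pytest.fixture(scope="session")
def power_batch():
    """100 delta=0.1 pipelines (parameter recovery)."""
    return [
        run_replicate(30_000 + i, delta=0.1, with_ols=True) for i in range(100)
    ]


@pytest.fixture(scope="session")
def identical_cohort_batch():
    """200 delta=0 pipelines with identical ancestry in both cohorts."""
    return [
        run_replicate(40_000 + i, delta=0.0, n_snps=5_000, identical_cohorts=True)
        for i in range(200)
    ]


@pytest.fixture(scope="session")
def scored_delta_batch():
    """100 tiny delta=0 scoring runs with binomial SEs."""
    return [run_scored_delta_replicate(50_000 + i) for i in range(100)]
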