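"""DAF computation, matched resampling, and the corrected ΔPRS z-score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from admixprs import (
    DafCorrection,
    MISSING,
    NullDistribution,
    SimulationConfig,
    compute_daf,
    corrected_delta_prs,
    corrected_z_score,
    daf_matched_null,
    daf_matched_sample,
    generate_study,
    trait_daf_distribution,
)
from admixprs.prs import per_snp_count_deltas

from conftest import make_matrix


class TestComputeDaf:
    def test_ancestral_ref_counts_alt_alleles(self):
        m = make_matrix([[0], [1], [2]], ancestral=["A"])  # ref A, alt G
        daf = compute_daf(m, {"all": None})
        assert daf.frequencies.loc["s0", "all"] == pytest.approx(0.5)
        assert daf.derived_allele.loc["s0"] == "G"

    def test_ancestral_alt_takes_complement(self):
        m = make_matrix([[0], [1], [2]], ancestral=["G"])
        daf = compute_daf(m, {"all": None})
        assert daf.frequencies.loc["s0", "all"] == pytest.approx(0.5)
        assert daf.derived_allele.loc["s0"] == "A"

    def test_asymmetric_case_complementarity(self):
        m_ref = make_matrix([[2], [2], [1]], ancestral=["A"])
        m_alt = make_matrix([[2], [2], [1]], ancestral=["G"])
        d_ref = compute_daf(m_ref, {"all": None}).frequencies.loc["s0", "all"]
        d_alt = compute_daf(m_alt, {"all": None}).frequencies.loc["s0", "all"]
        assert d_ref == pytest.approx(5 / 6)
        assert d_alt == pytest.approx(1 / 6)

    def test_unknown_ancestral_excluded_and_counted(self):
        m = make_matrix([[0, 1], [1, 1]], ancestral=["A", None])
        daf = compute_daf(m, {"all": None})
        assert list(daf.frequencies.index) == ["s0"]
        assert daf.n_excluded_unpolarized == 1

    def test_missing_calls_shrink_the_denominator(self):
        m = make_matrix([[1], [MISSING], [2]], ancestral=["A"])
        daf = compute_daf(m, {"all": None})
        assert daf.frequencies.loc["s0", "all"] == pytest.approx(3 / 4)

    def test_zero_called_population_excludes_snp(self):
        m = make_matrix([[MISSING], [1]], ancestral=["A"])
        daf = compute_daf(m, {"a": ["ind0"], "b": ["ind1"]})
        assert daf.frequencies.empty
        assert daf.n_excluded_uncalled == 1

    def test_estimates_match_simulator_truth(self):
        """DAF estimated from an unadmixed cohort tracks the generating
        frequency within binomial sampling error."""
        config = SimulationConfig(
            n_snps=200, n_individuals=400, cohorts={"afr": (1e6, 1e-6, 1e-6)}, seed=5
        )
        from admixprs import simulate_cohort, simulate_frequencies

        freqs = simulate_frequencies(config, 1)
        matrix, _ = simulate_cohort(freqs, config, "afr", 2)
        daf = compute_daf(matrix, {"afr": None})
        est = daf.frequencies["afr"].to_numpy()
        q = freqs.q["AFR"]
        se = np.sqrt(q * (1 - q) / (2 * 400))
        assert np.mean(np.abs(est - q) <= 4 * se + 1e-9) > 0.99


class TestTraitDafDistribution:
    def test_single_occupied_bin(self):
        m = make_matrix([[1], [1], [1]], ancestral=["A"])
        daf = compute_daf(m, {"source": None})
        dist = trait_daf_distribution(daf, ["s0"], "source")
        assert dist.counts.sum() == 1
        assert dist.counts[dist.bin_of([0.5])[0]] == 1

    def test_hand_binned_counts(self):
        """20 listed DAFs land in hand-computed 0.05-wide bins."""
        values = [0.00, 0.01, 0.049, 0.05, 0.07, 0.12, 0.20, 0.24, 0.33, 0.41,
                  0.50, 0.52, 0.58, 0.63, 0.77, 0.81, 0.88, 0.93, 0.97, 1.00]
        # build a matrix whose allele counts reproduce these DAFs exactly:
        # 50 individuals -> DAF = k/100 for k derived alleles
        n_ind = 50
        cols = []
        for v in values:
            k = round(v * 100)
            col = np.zeros(n_ind, dtype=np.int16)
            col[: k // 2] = 2
            if k % 2:
                col[k // 2] = 1
            cols.append(col)
        m = make_matrix(np.column_stack(cols), ancestral=["A"] * len(values))
        daf = compute_daf(m, {"source": None})
        dist = trait_daf_distribution(daf, [f"s{j}" for j in range(len(values))], "source")
        expected = np.zeros(20, dtype=int)
        for v in values:
            b = min(int(np.floor(round(v * 100) / 5)), 19)
            expected[b] += 1
        assert dist.counts.tolist() == expected.tolist()
        assert dist.counts.sum() == 20

    def test_uniform_dafs_spread_across_bins(self):
        rng = np.random.default_rng(0)
        n = 2000
        k = rng.integers(0, 101, size=n)
        cols = np.zeros((50, n), dtype=np.int16)
        for j, kk in enumerate(k):
            cols[: kk // 2, j] = 2
            if kk % 2:
                cols[kk // 2, j] = 1
        m = make_matrix(cols, ancestral=["A"] * n)
        daf = compute_daf(m, {"source": None})
        dist = trait_daf_distribution(daf, [f"s{j}" for j in range(n)], "source")
        assert dist.counts.min() > 0.5 * dist.counts.mean()

    def test_empty_intersection_is_fatal(self):
        m = make_matrix([[1]], ancestral=["A"])
        daf = compute_daf(m, {"source": None})
        with pytest.raises(ValueError, match="no trait SNP"):
            trait_daf_distribution(daf, ["absent"], "source")

    def test_bad_bin_width_is_fatal(self):
        m = make_matrix([[1]], ancestral=["A"])
        daf = compute_daf(m, {"source": None})
        with pytest.raises(ValueError, match="tile"):
            trait_daf_distribution(daf, ["s0"], "source", bin_width=0.07)


@pytest.fixture(scope="module")
def parts():
    study = generate_study(
        SimulationConfig(n_snps=3_000, n_individuals=80, n_risk_snps=80, seed=21)
    )
    masks = list(study.cohort_masks.values())
    daf = compute_daf(
        study.genotypes, {"a": masks[0], "b": masks[1], "source": masks[1]}
    )
    trait_ids = [a.id for a in study.associations]
    dist = trait_daf_distribution(daf, trait_ids, "source")
    catalog_ids = study.catalog["id"].tolist()
    return study, masks, daf, dist, trait_ids, catalog_ids


class TestMatchedSampling:
    def test_sampled_set_histogram_matches_trait_histogram_exactly(self, parts):
        study, masks, daf, dist, trait_ids, catalog_ids = parts
        for seed in range(5):
            sample = daf_matched_sample(catalog_ids, dist, daf, 0.56, seed)
            got = daf.frequencies.loc[sample["id"], "source"].to_numpy()
            assert dist.bin_of(got).tolist() != []
            counts = np.bincount(dist.bin_of(got), minlength=dist.n_bins)
            assert counts.tolist() == dist.counts.tolist()
            assert sample["id"].is_unique

    def test_degenerate_single_bin_reduces_to_uniform_sampling(self, parts):
        study, masks, daf, dist_, trait_ids, catalog_ids = parts
        dist = trait_daf_distribution(daf, trait_ids, "source", bin_width=1.0)
        assert dist.n_bins == 1
        sample = daf_matched_sample(catalog_ids, dist, daf, 0.56, 3)
        assert len(sample) == len(trait_ids)

    def test_derived_effect_fraction_preserved_over_many_sets(self, parts):
        study, masks, daf, dist, trait_ids, catalog_ids = parts
        rng = np.random.default_rng(9)
        fractions = [
            daf_matched_sample(catalog_ids, dist, daf, 0.56, rng)["effect_is_derived"].mean()
            for _ in range(300)
        ]
        assert np.mean(fractions) == pytest.approx(0.56, abs=0.01)

    def test_underfilled_bin_is_fatal_with_bin_identity(self, parts):
        study, masks, daf, dist, trait_ids, catalog_ids = parts
        b = int(np.nonzero(dist.counts)[0][0])
        lo, hi = dist.edges[b], dist.edges[b + 1]
        source = daf.frequencies["source"]
        thin = [
            i for i in catalog_ids
            if i in daf and not (lo <= source.loc[i] < hi)
        ]
        with pytest.raises(ValueError, match="catalog SNP"):
            daf_matched_sample(thin, dist, daf, 0.56, 0)

    def test_vectorized_null_agrees_with_per_set_sampling(self, parts):
        """The bulk null builder and the one-set-at-a-time protocol draw from
        the same distribution (moments agree within Monte-Carlo error)."""
        study, masks, daf, dist, trait_ids, catalog_ids = parts
        null = daf_matched_null(
            study.genotypes, catalog_ids, dist, daf, masks[0], masks[1],
            derived_effect_fraction=0.56, n_draws=4_000, seed=100,
        )
        rng = np.random.default_rng(101)
        derived, _ = study.genotypes.derived_dosages()
        loop_vals = []
        for _ in range(400):
            sample = daf_matched_sample(catalog_ids, dist, daf, 0.56, rng)
            idx = study.genotypes.snp_indices(sample["id"])
            d = derived[:, idx].astype(float)
            d[d == MISSING] = 0.0
            eff = np.where(sample["effect_is_derived"].to_numpy()[None, :], d, 2.0 - d)
            loop_vals.append(eff[masks[0]].sum(axis=1).mean() - eff[masks[1]].sum(axis=1).mean())
        loop_vals = np.array(loop_vals)
        assert null.mean == pytest.approx(
            loop_vals.mean(), abs=4 * loop_vals.std() / np.sqrt(400)
        )
        assert null.sd == pytest.approx(loop_vals.std(), rel=0.15)

    def test_matched_null_is_seed_reproducible(self, parts):
        study, masks, daf, dist, trait_ids, catalog_ids = parts
        kwargs = dict(derived_effect_fraction=0.56, n_draws=500, seed=77)
        n1 = daf_matched_null(study.genotypes, catalog_ids, dist, daf, masks[0], masks[1], **kwargs)
        n2 = daf_matched_null(study.genotypes, catalog_ids, dist, daf, masks[0], masks[1], **kwargs)
        np.testing.assert_array_equal(n1.samples, n2.samples)


class TestCorrectedDeltaPrs:
    def test_worked_example_magnitude(self):
        """obs -2.08 against a null of mean -0.16, SD 1.25 gives a corrected
        score of magnitude 1.54 at two decimals."""
        z = corrected_z_score(-2.08, -0.16, 1.25)
        assert z == pytest.approx(-1.536)
        assert round(abs(z), 2) == 1.54

    def test_observation_at_null_mean_gives_zero(self):
        rng = np.random.default_rng(0)
        null = NullDistribution.from_samples(rng.normal(0.5, 1, 1000), 0, "daf_matched")
        res = corrected_delta_prs(null.mean, null)
        assert res.corrected_z == 0.0

    def test_standard_null_is_identity(self):
        samples = np.array([-1.0, 1.0])  # mean 0, sd 1
        null = NullDistribution.from_samples(samples, 0, "daf_matched")
        res = corrected_delta_prs(0.73, null)
        assert res.corrected_z == pytest.approx(0.73)

    def test_zero_sd_null_is_fatal(self):
        null = NullDistribution.from_samples(np.zeros(10), 0, "daf_matched")
        with pytest.raises(ValueError, match="positive"):
            corrected_delta_prs(1.0, null)

    def test_scale_mismatch_is_fatal(self):
        from admixprs.prs import DeltaPrs

        null = NullDistribution.from_samples(np.array([-1.0, 1.0]), 0, "daf_matched")
        obs = DeltaPrs("A", "B", "normalized", 0.2, 10, 10)
        with pytest.raises(ValueError, match="scale"):
            corrected_delta_prs(obs, null)

    @given(
        st.floats(min_value=0.1, max_value=50.0),
        st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_affine_invariance_of_the_z_score(self, c, b):
        """Rescaling all scores by c and shifting by b transforms obs and
        null identically, leaving the corrected z unchanged."""
        rng = np.random.default_rng(4)
        samples = rng.normal(-0.2, 1.3, 500)
        obs = -2.0
        null = NullDistribution.from_samples(samples, 0, "daf_matched")
        base = corrected_delta_prs(obs, null).corrected_z
        # a per-individual affine map y -> c*y + b shifts a two-population
        # difference to c*delta, for observed and null alike
        null2 = NullDistribution.from_samples(c * samples, 0, "daf_matched")
        scaled = corrected_delta_prs(c * obs, null2).corrected_z
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_normal_p_reported_as_secondary(self):
        rng = np.random.default_rng(5)
        null = NullDistribution.from_samples(rng.normal(0, 1, 20_000), 0, "daf_matched")
        res = corrected_delta_prs(1.0, null, alternative="greater")
        assert res.empirical_p == pytest.approx(res.p_normal, abs=0.02)
        frame = res.as_frame()
        assert {"obs_delta_prs", "corrected_z", "empirical_p"} <= set(frame.columns)


def test_daf_correction_estimator_end_to_end(small_study):
    masks = list(small_study.cohort_masks.values())
    model = DafCorrection(n_draws=1_500, random_state=3, alternative="greater").fit(
        small_study.genotypes,
        associations=small_study.associations,
        catalog_ids=small_study.catalog["id"].tolist(),
        pop_a=masks[0],
        pop_b=masks[1],
        source_pop=masks[1],
    )
    assert model.null_.provenance == "daf_matched"
    assert model.null_.sd > 0
    assert model.result_.corrected_z == pytest.approx(
        (model.observed_delta_ - model.null_.mean) / model.null_.sd
    )
    assert 0 < model.empirical_p_ <= 1
    assert 0 <= model.derived_effect_fraction_ <= 1
    assert model.n_trait_snps_ == len(small_study.associations)


def test_bias_removal_shifts_matched_null_not_permutation_null(bias_batch):
    """Under ascertainment-biased trait selection with no true differential,
    the matched null tracks the biased observation while the plain
    permutation null does not."""
    obs = np.array([r["obs_delta"] for r in bias_batch])
    matched = np.array([r["null_mean"] for r in bias_batch])
    perm = np.array([r["perm_mean"] for r in bias_batch])
    assert abs(np.mean(obs - matched)) < abs(np.mean(obs - perm))
    assert abs(np.mean(perm)) < 0.5  # permutation null stays near zero
    assert np.mean(obs) < -0.3  # the emulated bias is real
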