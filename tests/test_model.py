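import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from mexmod import (
    AlterationMatrix,
    MEParameters,
    brute_force_observation_likelihood,
    count_profile,
    dataset_log_likelihood,
    observed_count_probabilities,
    simulate_independence_dataset,
    simulate_me_dataset,
)
from mexmod.matrix import CountProfile

from conftest import random_parameters


class TestParameterValidation:
    def test_error_rates_must_stay_below_half(self):
        with pytest.raises(ValueError):
            MEParameters(0.5, 0.1, fp_rate=0.5, variant="full")
        with pytest.raises(ValueError):
            MEParameters(0.5, 0.1, fn_rate=0.6, variant="full")

    def test_variant_constraints(self):
        with pytest.raises(ValueError):
            MEParameters(0.5, 0.1, fp_rate=0.1, variant="no_errors")
        with pytest.raises(ValueError):
            MEParameters(0.5, 0.1, fn_rate=0.1, variant="fp_only")


class TestCountClassProbabilities:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (MEParameters(0.0, 0.3), (1, 0, 0, 0)),
            (MEParameters(1.0, 0.0), (0, 1, 0, 0)),
            (MEParameters(0.5, 0.2), (0.5, 0.32, 0.16, 0.02)),
        ],
        ids=["no_coverage", "pure_exclusivity", "half_covered_impure"],
    )
    def test_known_values_k3(self, params, expected):
        np.testing.assert_allclose(
            observed_count_probabilities(params, 3), expected, atol=1e-12
        )

    def test_normalization_over_parameter_grid(self):
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        rates = [0.0, 0.1, 0.49]
        for k in range(1, 11):
            for cov, imp, fp, fn in itertools.product(grid, grid, rates, rates):
                p = observed_count_probabilities(
                    MEParameters(cov, imp, fp, fn, variant="full"), k
                )
                assert abs(p.sum() - 1.0) < 1e-12
                assert (p >= 0).all()

    def test_matches_enumeration_oracle_per_class(self):
        """Closed-form class probabilities equal the sum of brute-force
        observation likelihoods over each count class (k <= 6)."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            k = int(rng.integers(1, 7))
            params = random_parameters(rng)
            closed = observed_count_probabilities(params, k)
            by_class = np.zeros(k + 1)
            for obs in itertools.product((0, 1), repeat=k):
                by_class[sum(obs)] += brute_force_observation_likelihood(obs, params)
            np.testing.assert_allclose(closed, by_class, atol=1e-10)


class TestBruteForceObservationLikelihood:
    def test_uncovered_all_zero(self):
        assert brute_force_observation_likelihood(
            [0, 0, 0], MEParameters(0.5, 0.3)
        ) == pytest.approx(0.5)

    def test_pure_exclusivity_is_uniform_over_single_ones(self):
        params = MEParameters(1.0, 0.0)
        k = 4
        for obs in itertools.product((0, 1), repeat=k):
            expected = 1 / k if sum(obs) == 1 else 0.0
            assert brute_force_observation_likelihood(obs, params) == pytest.approx(
                expected, abs=1e-12
            )

    def test_exchangeability(self):
        """The likelihood depends only on the number of 1s, not their
        positions."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            params = random_parameters(rng)
            obs = rng.integers(0, 2, size=5)
            perm = rng.permutation(obs)
            assert brute_force_observation_likelihood(
                obs, params
            ) == pytest.approx(
                brute_force_observation_likelihood(perm, params), rel=1e-12
            )

    def test_enumeration_bound(self):
        with pytest.raises(ValueError, match="k <= 12"):
            brute_force_observation_likelihood([0] * 13, MEParameters(0.5, 0.1))


class TestDatasetLogLikelihood:
    def test_single_uncovered_row(self):
        profile = CountProfile(counts=np.array([1, 0, 0, 0]), n=1, k=3)
        assert dataset_log_likelihood(
            profile, MEParameters(0.5, 0.2)
        ) == pytest.approx(np.log(0.5))

    def test_additivity_over_concatenation(self):
        params = MEParameters(0.7, 0.15)
        a, _ = simulate_me_dataset(params, 50, 4, seed=1)
        b, _ = simulate_me_dataset(params, 70, 4, seed=2)
        both = AlterationMatrix.from_values(
            np.vstack([a.values, b.values])
        )
        ll = dataset_log_likelihood(count_profile(both), params)
        ll_parts = dataset_log_likelihood(
            count_profile(a), params
        ) + dataset_log_likelihood(count_profile(b), params)
        assert ll == pytest.approx(ll_parts, rel=1e-12)

    def test_equals_per_row_oracle_sum(self, toy_matrix):
        params = MEParameters(0.75, 1 / 6)
        expected = sum(
            np.log(brute_force_observation_likelihood(row, params))
            for row in toy_matrix.values
        )
        assert dataset_log_likelihood(
            count_profile(toy_matrix), params
        ) == pytest.approx(expected, rel=1e-12)

    def test_zero_probability_class_gives_minus_inf(self):
        profile = CountProfile(counts=np.array([0, 0, 1, 0]), n=1, k=3)
        assert dataset_log_likelihood(profile, MEParameters(1.0, 0.0)) == -np.inf


class TestMESimulator:
    def test_pure_pattern_has_one_alteration_per_row(self):
        matrix, latent = simulate_me_dataset(MEParameters(1.0, 0.0), 200, 5, seed=3)
        assert (matrix.values.sum(axis=1) == 1).all()
        assert (latent.covered == 1).all()

    def test_no_coverage_no_fp_gives_all_zero(self):
        matrix, _ = simulate_me_dataset(MEParameters(0.0, 0.5), 50, 4, seed=4)
        assert matrix.values.sum() == 0

    def test_deterministic_given_seed(self):
        params = MEParameters(0.6, 0.1, 0.05, 0.02, variant="full")
        a, la = simulate_me_dataset(params, 100, 6, seed=11)
        b, lb = simulate_me_dataset(params, 100, 6, seed=11)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(la.true_alterations, lb.true_alterations)

    def test_latent_state_consistent_with_observation_channel(self):
        params = MEParameters(0.6, 0.1, variant="no_errors")
        matrix, latent = simulate_me_dataset(params, 300, 5, seed=5)
        np.testing.assert_array_equal(matrix.values, latent.true_alterations)

    def test_count_profile_matches_closed_form(self):
        """Empirical count-class frequencies agree with the closed-form
        probabilities (goodness-of-fit at level 0.01, n = 10^4)."""
        params = MEParameters(0.6, 0.1, 0.05, 0.0, variant="fp_only")
        matrix, _ = simulate_me_dataset(params, 10_000, 5, seed=6)
        observed = count_profile(matrix).counts
        expected = observed_count_probabilities(params, 5) * 10_000
        keep = expected > 5
        stat, p = chisquare(
            observed[keep], expected[keep] * observed[keep].sum() / expected[keep].sum()
        )
        assert p > 0.01


class TestIndependenceSimulator:
    @pytest.mark.parametrize("freq, value", [(0.0, 0), (1.0, 1)])
    def test_degenerate_frequencies(self, freq, value):
        m = simulate_independence_dataset([freq] * 3, 20, seed=8)
        assert (m.values == value).all()

    def test_column_means_near_frequencies(self):
        freqs = np.array([0.1, 0.3])
        m = simulate_independence_dataset(freqs, 10_000, seed=9)
        se = np.sqrt(freqs * (1 - freqs) / 10_000)
        assert (np.abs(m.values.mean(axis=0) - freqs) < 3 * se).all()
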