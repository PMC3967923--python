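import itertools

import numpy as np
import pytest

from mexmod import (
    AlterationMatrix,
    EMOptions,
    MEParameters,
    brute_force_posterior,
    count_profile,
    e_step_expectations,
    em_fit,
    fit_independence,
    fit_reduced,
    simulate_me_dataset,
)

from conftest import random_parameters


def reduced_class_log_likelihood(profile, coverage, impurity):
    """Error-free ME log-likelihood over count classes, written directly
    from the class probabilities (independent check of the closed forms)."""
    from scipy.stats import binom

    k = profile.k
    m = np.arange(k + 1)
    p = np.empty(k + 1)
    p[0] = 1 - coverage
    p[1:] = coverage * binom.pmf(m[1:] - 1, k - 1, impurity)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    mask = profile.counts > 0
    if np.isneginf(logp[mask]).any():
        return -np.inf
    return float((profile.counts[mask] * logp[mask]).sum())


class TestFitReduced:
    def test_toy_matrix_closed_form(self, toy_matrix):
        fit = fit_reduced(toy_matrix)
        assert fit.params.coverage == pytest.approx(0.75)
        assert fit.params.impurity == pytest.approx(1 / 6)

    def test_toy_matrix_against_grid_maximization(self, toy_matrix):
        profile = count_profile(toy_matrix)
        grid = np.linspace(1e-6, 1 - 1e-6, 400)
        best = max(
            ((c, d) for c in grid for d in grid),
            key=lambda cd: reduced_class_log_likelihood(profile, *cd),
        )
        assert abs(best[0] - 0.75) < 0.01
        assert abs(best[1] - 1 / 6) < 0.01

    def test_perfectly_exclusive_matrix(self):
        fit = fit_reduced(AlterationMatrix.from_values(np.eye(4, dtype=int)))
        assert fit.params.coverage == 1.0
        assert fit.params.impurity == 0.0

    def test_all_zero_matrix_boundary(self):
        fit = fit_reduced(AlterationMatrix.from_values(np.zeros((5, 3), int)))
        assert fit.params.coverage == 0.0
        assert fit.params.impurity == 0.0

    def test_all_one_matrix_boundary(self):
        fit = fit_reduced(AlterationMatrix.from_values(np.ones((5, 3), int)))
        assert fit.params.coverage == 1.0
        assert fit.params.impurity == 1.0

    def test_maximizes_likelihood_on_random_datasets(self):
        """The closed forms attain the grid maximum of the error-free
        log-likelihood on 50 random datasets (k=5, n=200, 200x200 grid)."""
        rng = np.random.default_rng(31)
        grid = np.linspace(1e-9, 1 - 1e-9, 200)
        for _ in range(50):
            params = random_parameters(rng, with_errors=False)
            matrix, _ = simulate_me_dataset(params, 200, 5, seed=int(rng.integers(2**31)))
            profile = count_profile(matrix)
            fit = fit_reduced(profile)
            ll_hat = reduced_class_log_likelihood(
                profile, fit.params.coverage, fit.params.impurity
            )
            # separable: maximize over the grid coordinate-wise
            ll_grid = max(
                reduced_class_log_likelihood(profile, c, fit.params.impurity)
                for c in grid
            )
            ll_grid_d = max(
                reduced_class_log_likelihood(profile, fit.params.coverage, d)
                for d in grid
            )
            assert ll_hat >= ll_grid - 1e-9
            assert ll_hat >= ll_grid_d - 1e-9


class TestFitIndependence:
    def test_frequencies_are_column_means(self, toy_matrix):
        fit = fit_independence(toy_matrix)
        np.testing.assert_allclose(fit.params.frequencies, [0.5, 0.5, 0.0])

    def test_all_one_matrix_loglik_zero(self):
        fit = fit_independence(AlterationMatrix.from_values(np.ones((4, 3), int)))
        np.testing.assert_allclose(fit.params.frequencies, 1.0)
        assert fit.log_likelihood == 0.0

    def test_loglik_value(self, toy_matrix):
        # frequencies (.5, .5, 0): the two informative columns contribute
        # 4 rows * log .5 each; the empty column contributes 0
        fit = fit_independence(toy_matrix)
        assert fit.log_likelihood == pytest.approx(8 * np.log(0.5))


class TestEStep:
    def test_observable_coverage_without_errors(self):
        params = MEParameters(0.4, 0.2)
        for m in range(1, 5):
            a, b, c, d, e = e_step_expectations(m, 4, params)
            assert a == pytest.approx(1.0)
            assert c == pytest.approx(0.0)
            assert d == pytest.approx(0.0)
        a, *_ = e_step_expectations(0, 4, params)
        assert a == pytest.approx(0.0)

    def test_pure_exclusive_observation(self):
        a, b, c, d, e = e_step_expectations(1, 3, MEParameters(1.0, 0.0))
        assert (a, b, c, d, e) == pytest.approx((1, 0, 0, 0, 1))

    def test_matches_enumeration_oracle(self):
        """Closed-form posterior expectations equal exhaustive latent-state
        enumeration for all count classes, >= 100 random parameter draws."""
        rng = np.random.default_rng(1234)
        for _ in range(100):
            k = int(rng.integers(2, 7))
            params = random_parameters(rng)
            for m in range(k + 1):
                closed = np.array(e_step_expectations(m, k, params))
                obs = [1] * m + [0] * (k - m)
                brute = np.array(brute_force_posterior(obs, params))
                np.testing.assert_allclose(closed, brute, atol=1e-10)
                assert ((closed >= -1e-12) & (closed <= k + 1e-12)).all()
                assert closed[4] == pytest.approx(closed[0] + closed[1], abs=1e-10)

    def test_rejects_out_of_range_class(self):
        with pytest.raises(ValueError):
            e_step_expectations(5, 4, MEParameters(0.5, 0.1))


class TestEMFit:
    def test_known_errors_with_zero_rates_matches_reduced(self):
        matrix, _ = simulate_me_dataset(MEParameters(0.6, 0.1), 500, 5, seed=21)
        em = em_fit(
            matrix, variant="known_errors",
            fixed={"fp_rate": 0.0, "fn_rate": 0.0}, seed=0,
        )
        red = fit_reduced(matrix)
        assert em.params.coverage == pytest.approx(red.params.coverage, abs=1e-6)
        assert em.params.impurity == pytest.approx(red.params.impurity, abs=1e-6)
        assert em.log_likelihood == pytest.approx(red.log_likelihood, abs=1e-6)

    def test_loglik_trace_monotone(self):
        true = MEParameters(0.5, 0.1, 0.05, 0.0, variant="fp_only")
        matrix, _ = simulate_me_dataset(true, 800, 5, seed=22)
        fit = em_fit(matrix, variant="fp_only", seed=1)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-8).all()

    def test_parameter_recovery_known_errors(self):
        """Median coverage/impurity estimates over 20 replicates within
        +/- 0.05 of truth at k=5, n=1000, fp=0.05 known."""
        true = MEParameters(0.6, 0.05, 0.05, 0.0, variant="fp_only")
        covs, imps = [], []
        for s in range(20):
            matrix, _ = simulate_me_dataset(true, 1000, 5, seed=400 + s)
            fit = em_fit(
                matrix, variant="known_errors",
                fixed={"fp_rate": 0.05, "fn_rate": 0.0}, seed=s,
            )
            covs.append(fit.params.coverage)
            imps.append(fit.params.impurity)
        assert abs(np.median(covs) - 0.6) < 0.05
        assert abs(np.median(imps) - 0.05) < 0.05

    def test_nested_variant_likelihood_dominance(self):
        """full >= fp_only >= reduced log-likelihood on the same profile."""
        true = MEParameters(0.6, 0.1, 0.05, 0.0, variant="fp_only")
        matrix, _ = simulate_me_dataset(true, 500, 5, seed=23)
        opts = EMOptions(n_random_starts=5)
        ll_red = fit_reduced(matrix).log_likelihood
        ll_fp = em_fit(matrix, variant="fp_only", options=opts, seed=2).log_likelihood
        ll_full = em_fit(matrix, variant="full", options=opts, seed=2).log_likelihood
        assert ll_fp >= ll_red - 1e-6
        assert ll_full >= ll_fp - 1e-6

    def test_requires_fixed_rates_for_known_errors(self):
        matrix, _ = simulate_me_dataset(MEParameters(0.6, 0.1), 50, 4, seed=24)
        with pytest.raises(ValueError, match="fixed"):
            em_fit(matrix, variant="known_errors")

    def test_fit_result_serializable(self):
        matrix, _ = simulate_me_dataset(MEParameters(0.6, 0.1), 100, 4, seed=25)
        rec = fit_reduced(matrix).to_record()
        assert set(rec) >= {"coverage", "impurity", "log_likelihood", "variant"}
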