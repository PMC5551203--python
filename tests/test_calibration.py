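"""NSE / correlation metrics, controlled random search, adaptive Metropolis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pondnit.calibration import (
    combined_objective,
    mcmc_sample,
    nse,
    pearson_r,
    pseudo_search,
)
from pondnit.exceptions import ConfigurationError, InitializationError, UndefinedMetricError


class TestNse:
    def test_perfect_model(self):
        assert nse([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_mean_benchmark_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 6.0])
        assert nse(obs, np.full(4, obs.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # residual SS = 1, variance SS = 2
        assert nse([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedMetricError):
            nse([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        scale=st.floats(0.1, 100),
        shift=st.floats(-50, 50),
        seed=st.integers(0, 1000),
    )
    def test_affine_unit_invariance(self, scale, shift, seed):
        """Rescaling both series' units leaves NSE unchanged."""
        rng = np.random.default_rng(seed)
        obs = rng.normal(10, 3, 20)
        sim = obs + rng.normal(0, 1, 20)
        a = nse(obs, sim)
        b = nse(scale * obs + shift, scale * sim + shift)
        assert b == pytest.approx(a, rel=1e-9, abs=1e-9)


class TestPearson:
    def test_affine_relation_is_perfect(self):
        obs = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_r(obs, 2 * obs + 1) == pytest.approx(1.0)
        assert pearson_r(obs, -obs) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_series_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCombinedObjective:
    def test_equal_weights_mean(self):
        assert combined_objective([0.6, 0.9, 0.3]) == pytest.approx(0.6)

    def test_failure_sentinel(self):
        assert combined_objective([0.5, np.nan, 0.5]) == -np.inf
        assert combined_objective([0.5, -np.inf, 0.5]) == -np.inf

    def test_weights(self):
        assert combined_objective([1.0, 0.0, 0.0], weights=[1, 0, 0]) == 1.0


class TestPseudoSearch:
    def test_convex_recovery(self):
        """Quadratic peak recovered to within 1% of its location."""
        c = np.array([0.3, 0.6, 0.45, 0.52, 0.7])
        res = pseudo_search(
            lambda x: -np.sum((x - c) ** 2),
            np.zeros(5),
            np.ones(5),
            n_iter=500,
            seed=2,
        )
        assert np.all(np.abs(res.x - c) < 0.01)

    def test_all_candidates_feasible_and_deterministic(self):
        lower, upper = np.array([-1.0, 0.0]), np.array([1.0, 2.0])
        seen = []

        def f(x):
            seen.append(x.copy())
            return -np.sum(x**2)

        res1 = pseudo_search(f, lower, upper, n_iter=80, seed=7)
        assert all(np.all(x >= lower) and np.all(x <= upper) for x in seen)
        res2 = pseudo_search(lambda x: -np.sum(x**2), lower, upper, n_iter=80, seed=7)
        assert np.array_equal(res1.x, res2.x)
        assert res1.fun == res2.fun

    def test_trace_is_monotone_best_so_far(self):
        res = pseudo_search(lambda x: -np.sum(x**2), np.array([-1.0]), np.array([1.0]),
                            n_iter=60, seed=0)
        assert np.all(np.diff(res.trace) >= 0)

    def test_budget_below_population_rejected(self):
        with pytest.raises(ConfigurationError):
            pseudo_search(lambda x: 0.0, np.zeros(9), np.ones(9), n_iter=10)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            pseudo_search(lambda x: 0.0, np.ones(2), np.ones(2), n_iter=50)


class TestMcmc:
    def toy_gaussian(self, n=4000, seed=3):
        mu = np.array([0.5, -0.25])
        sd = np.array([0.2, 0.1])

        def logp(x):
            return -0.5 * np.sum(((x - mu) / sd) ** 2)

        chain = mcmc_sample(
            logp, np.array([0.4, -0.2]), np.array([-2.0, -2.0]), np.array([2.0, 2.0]),
            n_samples=n, seed=seed,
        )
        return chain, mu, sd

    def test_gaussian_target_mean_recovery(self):
        """Chain mean lands within 3 effective standard errors of the target."""
        chain, mu, sd = self.toy_gaussian()
        post = chain.posterior
        # generous autocorrelation allowance: tau ~ 40
        se = sd * np.sqrt(40.0 / len(post))
        assert np.all(np.abs(post.mean(axis=0) - mu) < 3 * se)
        assert 0.1 < chain.acceptance_rate < 0.6

    def test_split_half_stationarity(self):
        chain, mu, sd = self.toy_gaussian(n=6000, seed=11)
        post = chain.posterior
        half = len(post) // 2
        tol = 3 * sd * np.sqrt(40.0 / half)
        assert np.all(np.abs(post[:half].mean(axis=0) - post[half:].mean(axis=0)) < 2 * tol)

    def test_chain_contract(self):
        chain, _, _ = self.toy_gaussian(n=500, seed=1)
        assert len(chain) == 500
        assert np.all(chain.samples >= -2.0) and np.all(chain.samples <= 2.0)
        assert chain.burn_in == 100

    def test_determinism(self):
        a, _, _ = self.toy_gaussian(n=300, seed=9)
        b, _, _ = self.toy_gaussian(n=300, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_bad_initialization_rejected(self):
        with pytest.raises(InitializationError):
            mcmc_sample(lambda x: 0.0, [5.0], [0.0], [1.0], n_samples=10)
        with pytest.raises(InitializationError):
            mcmc_sample(lambda x: -np.inf, [0.5], [0.0], [1.0], n_samples=10)

    def test_aux_recording(self):
        """Tuple-returning targets populate objective and per-variable extras."""
        chain = mcmc_sample(
            lambda x: (-0.5 * x[0] ** 2, float(x[0]), np.array([1.0, 2.0, 3.0])),
            [0.1], [-1.0], [1.0], n_samples=50, seed=0,
        )
        assert chain.objective is not None and chain.aux.shape == (50, 3)
        assert np.array_equal(chain.objective, chain.samples[:, 0])


class TestModelFit:
    def test_fit_recovers_generating_parameters(self, small_fit, truth_params):
        """Best fit stays within the +/-10% box and near the truth."""
        best = small_fit.params.free_values()
        truth = truth_params.free_values()
        assert np.all(np.abs(best / truth - 1) <= 0.10 + 1e-9)
        assert small_fit.objective_value > 0.5

    def test_best_beats_or_matches_truth_objective(self, small_model, small_fit, truth_params):
        obj_truth = small_model.objective(truth_params.free_values())
        assert small_fit.objective_value >= obj_truth - 0.02

    def test_fit_tables_and_summary(self, small_fit):
        assert list(small_fit.nse.index) == ["ON", "NH3", "NO3"]
        assert {"calibration", "validation"} <= set(small_fit.nse.columns)
        assert np.all(small_fit.nse.to_numpy() <= 1.0)
        assert np.all(np.abs(small_fit.r.to_numpy()) <= 1.0)
        text = small_fit.summary()
        assert "theta" in text and "NSE" in text

    def test_unsolvable_vector_maps_to_minus_inf(self, small_model):
        bad = np.full(9, np.nan)
        assert small_model.objective(bad) == -np.inf
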