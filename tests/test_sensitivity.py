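"""Local/global sensitivity, collinearity and envelope analyses."""

import numpy as np
import pytest

from pondnit import (
    ModelParameters,
    ParameterBounds,
    PondModel,
    collinearity,
    global_sensitivity,
    local_sensitivity,
    mcmc_pair_stats,
    prediction_envelope,
)
from pondnit.calibration import ChainResult
from pondnit.parameters import FREE_PARAMETERS
from pondnit.series import ObservationSeries
from pondnit.synthetic import ScenarioConfig, generate_scenario


class LinearStub:
    """Analytically differentiable stand-in model (synthetic, for oracles):
    ON = theta * t, NH3 = Rs * t, NO3 = K1 + K2 * t."""

    def __init__(self):
        t = np.arange(1.0, 11.0)
        self.params = ModelParameters()
        self.observations = ObservationSeries(
            times=t, values=np.column_stack([t, t, t])
        )

    def predict(self, params, times):
        t = np.asarray(times, dtype=float)
        return np.column_stack(
            [params.theta * t, params.Rs * t, params.K1 + params.K2 * t]
        )


class TestLocalSensitivity:
    def test_linear_model_analytic_oracle(self):
        """Central differences are exact for linear observables."""
        stub = LinearStub()
        sens = local_sensitivity(stub, scaling="sd")
        t = stub.observations.times
        sigma = stub.observations.values.std(axis=0)
        expected_theta = stub.params.theta * t / sigma[0]
        got = sens.matrix["theta"].loc["ON"].to_numpy()
        assert got == pytest.approx(expected_theta, rel=1e-6)
        assert sens.L1["theta"] == pytest.approx(np.abs(sens.matrix["theta"]).mean())
        # NH3 and NO3 rows of theta's column are exactly zero
        assert np.allclose(sens.matrix["theta"].loc["NH3"], 0.0)

    def test_disabled_pathway_parameter_has_zero_column(self, small_data):
        # with nitrate uptake off (p2 = 0), K3 never enters the model
        forcing, obs, _ = small_data
        model = PondModel(forcing, obs, params=ModelParameters(p1=1.0, p2=0.0))
        sens = local_sensitivity(model)
        assert np.allclose(sens.matrix["K3"].to_numpy(), 0.0, atol=1e-10)
        assert sens.L1["K3"] == pytest.approx(0.0, abs=1e-10)
        assert sens.ranking["K3"] == 9  # lowest rank

    def test_yield_and_growth_rate_are_anti_collinear(self, small_model):
        """mun and Yn act only through mun/Yn, so their scaled sensitivities
        are exactly opposite."""
        sens = local_sensitivity(small_model)
        a = sens.matrix["mun"].to_numpy()
        b = sens.matrix["Yn"].to_numpy()
        rho = np.corrcoef(a, b)[0, 1]
        assert rho == pytest.approx(-1.0, abs=5e-3)  # finite-difference noise only

    def test_ranking_follows_l1(self, small_model):
        sens = local_sensitivity(small_model)
        ordered = sens.L1.sort_values(ascending=False)
        assert sens.ranking[ordered.index[0]] == 1
        assert np.all(sens.L2 >= 0) and np.all(sens.L1 >= 0)


class TestCollinearity:
    def test_single_parameter_gamma_is_one(self):
        S = np.random.default_rng(0).normal(size=(12, 4))
        table = collinearity(S, max_subset_size=1)
        assert np.allclose(table["gamma"], 1.0)

    def test_orthogonal_columns_gamma_one(self):
        S = np.eye(6)[:, :3]
        table = collinearity(S, max_subset_size=3)
        assert np.allclose(table["gamma"], 1.0)

    def test_duplicated_column_flagged_infinite(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=10)
        S = np.column_stack([col, col, rng.normal(size=10)])
        table = collinearity(S, max_subset_size=2)
        pair = table[(table["size"] == 2)]
        dup = pair[pair["subset"] == ("p0", "p1")]
        assert np.isinf(dup["gamma"].iloc[0])

    def test_zero_column_flagged_not_raised(self):
        S = np.column_stack([np.zeros(8), np.ones(8)])
        table = collinearity(S, max_subset_size=2)
        assert np.isinf(table[table["subset"] == ("p0",)]["gamma"].iloc[0])

    def test_brute_force_svd_oracle(self):
        """gamma equals 1/smallest singular value of the normalized columns."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            S = rng.normal(size=(10, 3))
            table = collinearity(S, max_subset_size=3)
            full = table[table["size"] == 3]["gamma"].iloc[0]
            Sn = S / np.linalg.norm(S, axis=0)
            expect = 1.0 / np.linalg.svd(Sn, compute_uv=False)[-1]
            assert full == pytest.approx(expect, rel=1e-9)

    def test_superset_monotonicity(self):
        rng = np.random.default_rng(3)
        S = rng.normal(size=(15, 4))
        table = collinearity(S, max_subset_size=3)
        lookup = {row.subset: row.gamma for row in table.itertuples()}
        for subset, gamma in lookup.items():
            for sup, gsup in lookup.items():
                if set(subset) < set(sup):
                    assert gsup >= gamma - 1e-9


@pytest.fixture(scope="module")
def tiny_model():
    forcing, obs, _ = generate_scenario(ScenarioConfig(duration_days=56, seed=21))
    return PondModel(forcing, obs)


class TestGlobalSensitivity:
    def narrow_bounds_except(self, center, wide, frac=0.10):
        c = center.free_values()
        lo, up = c * (1 - 1e-6), c * (1 + 1e-6)
        j = list(FREE_PARAMETERS).index(wide)
        lo[j], up[j] = c[j] * (1 - frac), c[j] * (1 + frac)
        return ParameterBounds(lower=lo, upper=up)

    def test_monotone_single_parameter_response(self, tiny_model):
        """With only theta free over a narrow window the mean-NH3 response is
        near-linear, so |r| approaches 1."""
        bounds = self.narrow_bounds_except(tiny_model.params, "theta", frac=0.03)
        gs = global_sensitivity(tiny_model, bounds, n=60, seed=5)
        assert gs.corr.loc["theta", "NH3"] < -0.99

    def test_inert_parameter_has_null_correlation(self, small_data):
        forcing, obs, _ = small_data
        model = PondModel(forcing, obs, params=ModelParameters(p1=1.0, p2=0.0))
        bounds = self.narrow_bounds_except(model.params, "K3")
        gs = global_sensitivity(model, bounds, n=60, seed=6)
        assert abs(gs.corr.loc["K3", "NH3"]) < 3 / np.sqrt(60) + 0.2

    def test_sample_count_and_bounds(self, tiny_model):
        bounds = ParameterBounds.around(tiny_model.params, 0.10)
        gs = global_sensitivity(tiny_model, bounds, n=40, seed=1)
        assert len(gs.samples) + gs.n_failed == 40
        assert np.all(gs.samples.to_numpy() >= bounds.lower)
        assert np.all(gs.samples.to_numpy() <= bounds.upper)
        assert np.all(np.abs(gs.corr.to_numpy()) <= 1.0)

    def test_minimum_sample_size_enforced(self, tiny_model):
        with pytest.raises(ValueError):
            global_sensitivity(tiny_model, ParameterBounds.around(tiny_model.params), n=10)


class TestPairStats:
    def make_chain(self, samples, burn_frac=0.2):
        n = len(samples)
        return ChainResult(
            samples=samples,
            logp=np.zeros(n),
            accepted=n,
            burn_in=int(burn_frac * n),
            param_names=("a", "b", "c")[: samples.shape[1]],
        )

    def test_independent_draws_have_null_correlations(self):
        rng = np.random.default_rng(8)
        chain = self.make_chain(rng.uniform(size=(1250, 3)))
        stats = mcmc_pair_stats(chain, bins=20)
        off = stats.corr.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(1000))

    def test_histograms_conserve_sample_count(self):
        rng = np.random.default_rng(9)
        chain = self.make_chain(rng.uniform(size=(500, 2)))
        stats = mcmc_pair_stats(chain, bins=20)
        assert np.all(stats.hist_counts.sum(axis=0) == len(chain.posterior))

    def test_correlated_pair_matches_analytic_value(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=40000)
        y = x + rng.normal(size=40000)  # rho = 1/sqrt(2)
        chain = self.make_chain(np.column_stack([x, y]), burn_frac=0.0)
        stats = mcmc_pair_stats(chain)
        assert stats.corr.iloc[0, 1] == pytest.approx(1 / np.sqrt(2), abs=0.02)

    def test_degenerate_column_flagged(self):
        rng = np.random.default_rng(11)
        samples = np.column_stack([rng.uniform(size=300), np.full(300, 2.0)])
        stats = mcmc_pair_stats(self.make_chain(samples, burn_frac=0.0))
        assert np.isnan(stats.corr.iloc[0, 1])


class TestPredictionEnvelope:
    def test_single_sample_collapses_bands(self, small_model, truth_params):
        chain = ChainResult(
            samples=truth_params.free_values()[None, :],
            logp=np.zeros(1),
            accepted=1,
            burn_in=0,
            param_names=FREE_PARAMETERS,
        )
        bands = prediction_envelope(small_model, chain, output_times=np.arange(7.0, 180, 7))
        for df in bands.values():
            assert np.array_equal(df["min"], df["max"])
            assert np.array_equal(df["min"], df["median"])

    def test_band_ordering(self, small_model, small_fit):
        bands = prediction_envelope(
            small_model, small_fit.chain, output_times=np.arange(7.0, 180, 7),
            max_samples=40,
        )
        for df in bands.values():
            assert np.all(df["min"] <= df["median"] + 1e-12)
            assert np.all(df["median"] <= df["max"] + 1e-12)

    def test_posterior_envelope_covers_generating_trajectory(self, recovery_experiment):
        """In the full recovery experiment the noiseless generating trajectory
        lies inside the posterior min/max band at >= 90% of weekly steps."""
        model, results, truth_result = recovery_experiment
        bands = prediction_envelope(
            model, results.chain, output_times=truth_result.times, max_samples=500
        )
        for k, v in enumerate(("ON", "NH3", "NO3")):
            df = bands[v]
            inside = (truth_result.states[:, k] >= df["min"] - 1e-9) & (
                truth_result.states[:, k] <= df["max"] + 1e-9
            )
            assert inside.mean() >= 0.9

    def test_all_simulations_failing_raises(self, small_model):
        # NaN samples cannot be simulated
        chain = ChainResult(
            samples=np.full((3, 9), np.nan),
            logp=np.zeros(3),
            accepted=0,
            burn_in=0,
            param_names=FREE_PARAMETERS,
        )
        from pondnit.exceptions import IntegrationError

        with pytest.raises(IntegrationError):
            prediction_envelope(small_model, chain, output_times=np.arange(7.0, 100, 7))
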