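"""Shared fixtures: small synthetic scenarios and a compact calibration run."""

import pytest

from pondnit import ModelParameters, ParameterBounds, PondGeometry, PondModel
from pondnit.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def geometry():
    return PondGeometry()


@pytest.fixture(scope="session")
def truth_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def small_scenario():
    """Half-year scenario: 26 weekly observations, 13 in the calibration window."""
    return ScenarioConfig(duration_days=182.0, seed=11)


@pytest.fixture(scope="session")
def small_data(small_scenario, truth_params):
    forcing, obs, truth_result = generate_scenario(small_scenario, truth_params)
    return forcing, obs, truth_result


@pytest.fixture(scope="session")
def small_model(small_data):
    forcing, obs, _ = small_data
    return PondModel(forcing, obs)


@pytest.fixture(scope="session")
def small_fit(small_model):
    """Compact two-stage calibration reused by chain-consuming tests."""
    bounds = ParameterBounds.around(small_model.params, 0.10)
    return small_model.fit(bounds=bounds, n_pseudo=60, n_mcmc=150, seed=5)


@pytest.fixture(scope="session")
def recovery_experiment(truth_params):
    """Full-scale parameter-recovery experiment: one year of synthetic data
    generated at the calibrated truth vector, fitted with 500 random-search
    evaluations and a 5000-sample adaptive Metropolis chain within +/-10%
    bounds.  Shared across the acceptance and envelope tests."""
    forcing, obs, truth_result = generate_scenario(ScenarioConfig(seed=1), truth_params)
    model = PondModel(forcing, obs)
    bounds = ParameterBounds.around(truth_params, 0.10)
    results = model.fit(bounds=bounds, n_pseudo=500, n_mcmc=5000, seed=1)
    return model, results, truth_result
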