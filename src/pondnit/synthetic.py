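"""Seeded synthetic forcing and observations for a tropical pilot pond.

The generator emulates the study conditions: a 20.5 x 1.2 x 0.80 m pond at
10 d hydraulic retention time, influent means 10.24 / 16.8 / 1.03 mg/L
(ON / NH3 / NO3), weekly effluent sampling over one year, and a tropical
climate with weak seasonality (28 +/- 3 degC annual sinusoid).

Structure of the random components:

* temperature and DO: annual sinusoid plus AR(1) day-to-day noise;
* pH: AR(1) fluctuation around the mean;
* influent concentrations: lognormal with the configured CV and AR(1)
  persistence (correlation time ~1 week) — septic-tank influent drifts on
  multi-week scales, and a 10-day-HRT CSTR averages away iid daily noise;
* observations: truth simulation sampled weekly with multiplicative
  Gaussian noise, clipped at zero.

Everything is reproducible from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .exceptions import ConfigurationError
from .parameters import ModelParameters, PondGeometry
from .series import ForcingSeries, ObservationSeries

__all__ = ["ScenarioConfig", "generate_forcing", "generate_observations", "generate_scenario"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of the synthetic pond scenario (defaults = study conditions)."""

    duration_days: float = 364.0
    sample_interval_days: float = 7.0
    influent_on: float = 10.24       # mg/L mean influent organic N
    influent_nh3: float = 16.8       # mg/L mean influent ammonia N
    influent_no3: float = 1.03       # mg/L mean influent nitrate N
    influent_cv: float = 0.15        # lognormal CV of influent concentrations
    influent_corr_days: float = 7.0   # AR(1) correlation time of influent
    temp_mean: float = 28.0          # degC
    temp_amplitude: float = 3.0      # degC annual sinusoid amplitude
    temp_noise_sd: float = 1.5       # degC AR(1) noise (synoptic weather)
    ph_mean: float = 7.8
    ph_sd: float = 0.2               # AR(1) fluctuation sd
    do_mean: float = 4.0             # mg/L
    do_amplitude: float = 1.0        # mg/L annual sinusoid amplitude
    do_noise_sd: float = 0.8         # mg/L AR(1) noise (algal activity, weather)
    env_corr_days: float = 5.0       # AR(1) correlation time of T/pH/DO noise
    obs_cv: float = 0.05             # multiplicative observation noise CV
    hrt_days: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_days < 2 * self.sample_interval_days:
            raise ConfigurationError("duration must cover at least two sampling intervals")
        for name in ("influent_on", "influent_nh3", "influent_no3", "temp_mean",
                     "ph_mean", "do_mean", "hrt_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("influent_cv", "obs_cv"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        for name in ("temp_amplitude", "temp_noise_sd", "ph_sd", "do_amplitude", "do_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**d)


def _ar1(rng: np.random.Generator, n: int, sd: float, corr_days: float) -> np.ndarray:
    """Stationary AR(1) series with unit time step, marginal sd ``sd``."""
    if sd == 0:
        return np.zeros(n)
    phi = np.exp(-1.0 / max(corr_days, 1e-6))
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    e = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i - 1]
    return x


def generate_forcing(
    config: ScenarioConfig, geometry: PondGeometry | None = None
) -> ForcingSeries:
    """Daily forcing records over ``[0, duration_days]``; seed-deterministic."""
    geometry = geometry if geometry is not None else PondGeometry()
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.duration_days + 0.5)
    n = t.size
    season = np.sin(2.0 * np.pi * t / 365.0)

    temp = config.temp_mean + config.temp_amplitude * season + _ar1(
        rng, n, config.temp_noise_sd, config.env_corr_days
    )
    ph = config.ph_mean + _ar1(rng, n, config.ph_sd, config.env_corr_days)
    do = config.do_mean + config.do_amplitude * season + _ar1(
        rng, n, config.do_noise_sd, config.env_corr_days
    )
    do = np.clip(do, 0.0, None)
    ph = np.clip(ph, 0.0, 14.0)

    sigma = np.sqrt(np.log1p(config.influent_cv**2))
    influent = {}
    for name, mean in (
        ("in_on", config.influent_on),
        ("in_nh3", config.influent_nh3),
        ("in_no3", config.influent_no3),
    ):
        z = _ar1(rng, n, 1.0, config.influent_corr_days) if sigma > 0 else np.zeros(n)
        influent[name] = mean * np.exp(sigma * z - 0.5 * sigma**2)

    q = np.full(n, geometry.volume / config.hrt_days)
    return ForcingSeries(
        times=t,
        temp=temp,
        ph=ph,
        do=do,
        in_on=influent["in_on"],
        in_nh3=influent["in_nh3"],
        in_no3=influent["in_no3"],
        q=q,
    )


def generate_observations(
    truth: ModelParameters,
    forcing: ForcingSeries,
    config: ScenarioConfig,
    geometry: PondGeometry | None = None,
):
    """Noisy weekly effluent observations from a truth-parameter simulation.

    Returns ``(observations, truth_result)`` — the noiseless truth
    trajectory is kept alongside for recovery experiments.
    """
    from .model import simulate

    geometry = geometry if geometry is not None else PondGeometry()
    t_lo, t_hi = forcing.span
    if t_hi - t_lo < config.duration_days - 1e-9:
        raise ConfigurationError("forcing does not span the scenario duration")
    sample_times = np.arange(
        t_lo + config.sample_interval_days, t_hi + 1e-9, config.sample_interval_days
    )
    init = (forcing.in_on[0], forcing.in_nh3[0], forcing.in_no3[0])
    truth_result = simulate(
        truth, forcing, geometry, init=init, output_times=sample_times
    )
    # noise stream separated from the forcing stream
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    noise = rng.normal(0.0, 1.0, size=truth_result.states.shape)
    values = np.clip(truth_result.states * (1.0 + config.obs_cv * noise), 0.0, None)
    obs = ObservationSeries(times=sample_times, values=values)
    return obs, truth_result


def generate_scenario(
    config: ScenarioConfig,
    truth: ModelParameters | None = None,
    geometry: PondGeometry | None = None,
):
    """Convenience: forcing + observations + truth trajectory in one call."""
    truth = truth if truth is not None else ModelParameters()
    geometry = geometry if geometry is not None else PondGeometry()
    forcing = generate_forcing(config, geometry)
    obs, truth_result = generate_observations(truth, forcing, config, geometry)
    return forcing, obs, truth_result
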