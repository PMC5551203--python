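"""End-to-end workflow driver: synthetic generation through GLUE reporting.

A :class:`RunConfig` (usually loaded from YAML) names the enabled stages;
:func:`run_pipeline` executes them in dependency order, writes each stage's
artifacts under the output directory and returns a JSON-serializable
manifest recording inputs, outputs, seeds and wall time per stage.  For
fixed seeds the pipeline is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .exceptions import ConfigurationError, StageError
from .glue import cdf_separation, dotty_data, evaluate_ensemble
from .model import PondModel
from .parameters import ModelParameters, ParameterBounds, PondGeometry
from .sensitivity import collinearity, global_sensitivity, local_sensitivity
from .synthetic import ScenarioConfig, generate_forcing, generate_observations

logger = logging.getLogger("pondnit")

ALL_STAGES = ("generate", "fit", "sens-local", "collin", "sens-global", "glue", "envelope")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "pondnit_out"
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    forcing_csv: str | None = None       # use existing data instead of generating
    observations_csv: str | None = None
    params: ModelParameters = field(default_factory=ModelParameters)
    geometry: PondGeometry = field(default_factory=PondGeometry)
    bounds_fraction: float = 0.10
    stages: tuple = ALL_STAGES
    n_pseudo: int = 500
    n_mcmc: int = 5000
    n_global: int = 1000
    max_subset_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if "generate" not in self.stages and (
            self.forcing_csv is None or self.observations_csv is None
        ):
            needs_obs = {"fit", "sens-local", "collin", "glue"} & set(self.stages)
            if self.forcing_csv is None or needs_obs:
                raise ConfigurationError(
                    "without the generate stage, forcing_csv (and observations_csv "
                    "for calibration stages) must be provided"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = pio.load_yaml(path)
        kw = dict(data)
        if "scenario" in kw:
            kw["scenario"] = ScenarioConfig.from_dict(kw["scenario"])
        if "params" in kw:
            kw["params"] = ModelParameters.from_dict(kw["params"])
        if "geometry" in kw:
            kw["geometry"] = pio.load_geometry(kw["geometry"])
        if "stages" in kw:
            kw["stages"] = tuple(kw["stages"])
        known = set(cls.__dataclass_fields__)
        unknown = set(kw) - known
        if unknown:
            raise ConfigurationError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**kw)

    def digest(self) -> str:
        payload = {
            "scenario": self.scenario.to_dict(),
            "params": self.params.to_dict(),
            "geometry": [self.geometry.length, self.geometry.width, self.geometry.depth],
            "bounds_fraction": self.bounds_fraction,
            "stages": list(self.stages),
            "n_pseudo": self.n_pseudo,
            "n_mcmc": self.n_mcmc,
            "n_global": self.n_global,
            "max_subset_size": self.max_subset_size,
            "seed": self.seed,
            "forcing_csv": self.forcing_csv,
            "observations_csv": self.observations_csv,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": [],
    }

    def record(stage, seed, inputs, outputs, t0):
        entry = {
            "stage": stage,
            "seed": seed,
            "inputs": inputs,
            "outputs": outputs,
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        manifest["stages"].append(entry)
        logger.info("[%s] done in %.2fs -> %s", stage, entry["wall_time_s"], outputs)

    def run_stage(stage, fn):
        t0 = time.perf_counter()
        try:
            seed, inputs, outputs = fn(t0)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        record(stage, seed, inputs, outputs, t0)

    # ------------------------------------------------------------- data
    forcing_path = out / "forcing.csv"
    obs_path = out / "observations.csv"
    if "generate" in config.stages:
        def _generate(t0):
            seed = config.seed
            scenario = ScenarioConfig.from_dict(
                {**config.scenario.to_dict(), "seed": seed}
            )
            forcing = generate_forcing(scenario, config.geometry)
            obs, truth = generate_observations(
                config.params, forcing, scenario, config.geometry
            )
            pio.write_forcing_csv(forcing, forcing_path)
            pio.write_observations_csv(obs, obs_path)
            truth.to_dataframe().to_csv(out / "truth_trajectory.csv", index=False,
                                        float_format="%.12g")
            return seed, [], [str(forcing_path), str(obs_path), str(out / "truth_trajectory.csv")]

        run_stage("generate", _generate)
    else:
        forcing_path = Path(config.forcing_csv)
        obs_path = Path(config.observations_csv) if config.observations_csv else None

    forcing = pio.read_forcing_csv(forcing_path)
    observations = pio.read_observations_csv(obs_path) if obs_path else None
    model = PondModel(
        forcing, observations, geometry=config.geometry, params=config.params
    )
    bounds = ParameterBounds.around(config.params, config.bounds_fraction)

    results = None
    if "fit" in config.stages:
        def _fit(t0):
            nonlocal results
            seed = config.seed + 10
            results = model.fit(
                bounds=bounds,
                n_pseudo=config.n_pseudo,
                n_mcmc=config.n_mcmc,
                seed=seed,
            )
            results.to_json(out / "fit.json")
            pio.write_chain_csv(results.chain_dataframe(), out / "chain.csv")
            (out / "summary.txt").write_text(results.summary() + "\n")
            return seed, [str(forcing_path), str(obs_path)], [
                str(out / "fit.json"), str(out / "chain.csv"), str(out / "summary.txt")
            ]

        run_stage("fit", _fit)

    sens = None
    if "sens-local" in config.stages or "collin" in config.stages:
        def _sens_local(t0):
            nonlocal sens
            center = results.params if results is not None else config.params
            sens = local_sensitivity(model, center)
            sens.matrix.reset_index().to_csv(out / "sensitivity_matrix.csv", index=False,
                                             float_format="%.12g")
            sens.summary_table().to_csv(out / "sensitivity_summary.csv",
                                        float_format="%.12g")
            return None, [str(forcing_path), str(obs_path)], [
                str(out / "sensitivity_matrix.csv"), str(out / "sensitivity_summary.csv")
            ]

        run_stage("sens-local", _sens_local)

    if "collin" in config.stages:
        def _collin(t0):
            table = collinearity(sens, max_subset_size=config.max_subset_size)
            table.assign(subset=table["subset"].map(lambda s: "+".join(s))).to_csv(
                out / "collinearity.csv", index=False, float_format="%.12g"
            )
            return None, [], [str(out / "collinearity.csv")]

        run_stage("collin", _collin)

    if "sens-global" in config.stages:
        def _sens_global(t0):
            seed = config.seed + 20
            gs = global_sensitivity(model, bounds, n=config.n_global, seed=seed)
            gs.corr.to_csv(out / "global_sensitivity_corr.csv", float_format="%.12g")
            samples = gs.samples.copy()
            for v in gs.responses.columns:
                samples[f"mean_{v.lower()}"] = gs.responses[v].to_numpy()
            samples.to_csv(out / "global_sensitivity_samples.csv", index=False,
                           float_format="%.12g")
            return seed, [str(forcing_path)], [
                str(out / "global_sensitivity_corr.csv"),
                str(out / "global_sensitivity_samples.csv"),
            ]

        run_stage("sens-global", _sens_global)

    if "glue" in config.stages:
        def _glue(t0):
            if results is None:
                raise ConfigurationError("glue stage requires the fit stage")
            ensemble = evaluate_ensemble(
                results.chain.samples, model, chain=results.chain
            )
            ensemble.to_dataframe().to_csv(out / "glue.csv", index=False,
                                           float_format="%.12g")
            sep = cdf_separation(ensemble)
            sep.table.to_csv(out / "glue_ks.csv", index=False, float_format="%.12g")
            dotty = dotty_data(ensemble)
            dotty.to_csv(out / "glue_dotty.csv", index=False, float_format="%.12g")
            return None, [str(out / "chain.csv")], [
                str(out / "glue.csv"), str(out / "glue_ks.csv"), str(out / "glue_dotty.csv")
            ]

        run_stage("glue", _glue)

    if "envelope" in config.stages:
        def _envelope(t0):
            if results is None:
                raise ConfigurationError("envelope stage requires the fit stage")
            bands = results.prediction_envelope()
            paths = []
            for v, df in bands.items():
                p = out / f"envelope_{v.lower()}.csv"
                df.to_csv(p, index=False, float_format="%.12g")
                paths.append(str(p))
            return None, [str(out / "chain.csv")], paths

        run_stage("envelope", _envelope)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
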