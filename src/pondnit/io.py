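"""CSV / YAML readers and writers with schema validation.

Column schemas
--------------
forcing:      time_d,temp_c,ph,do_mgl,in_on_mgl,in_nh3_mgl,in_no3_mgl,q_m3d
observations: time_d,on_mgl,nh3_mgl,no3_mgl
simulation:   time_d,on_mgl,nh3_mgl,no3_mgl,rm,rn,rs,rd,rv,r1,r2
chain:        the nine parameter columns + logp [+ objective, nse_*]

Headers are keyed by name (column order is free); numeric values round-trip
at 12 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .exceptions import SchemaError
from .parameters import FREE_PARAMETERS, ModelParameters, PondGeometry
from .series import FORCING_COLUMNS, OBS_COLUMNS, ForcingSeries, ObservationSeries
from .synthetic import ScenarioConfig

__all__ = [
    "read_forcing_csv",
    "write_forcing_csv",
    "read_observations_csv",
    "write_observations_csv",
    "read_chain_csv",
    "write_chain_csv",
    "load_yaml",
    "save_yaml",
    "load_scenario_config",
    "load_parameters",
    "load_geometry",
]

_FLOAT_FMT = "%.12g"


def _read_table(path, required: tuple) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_forcing_csv(path) -> ForcingSeries:
    df = _read_table(path, FORCING_COLUMNS)
    try:
        return ForcingSeries.from_dataframe(df)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_forcing_csv(forcing: ForcingSeries, path) -> None:
    forcing.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_observations_csv(path) -> ObservationSeries:
    df = _read_table(path, OBS_COLUMNS)
    try:
        return ObservationSeries.from_dataframe(df)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_observations_csv(obs: ObservationSeries, path) -> None:
    obs.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_chain_csv(path) -> pd.DataFrame:
    return _read_table(path, FREE_PARAMETERS)


def write_chain_csv(chain_df: pd.DataFrame, path) -> None:
    missing = set(FREE_PARAMETERS) - set(chain_df.columns)
    if missing:
        raise SchemaError(f"chain table missing parameter columns {sorted(missing)}")
    chain_df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: top-level YAML must be a mapping")
    return data


def save_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_scenario_config(path) -> ScenarioConfig:
    return ScenarioConfig.from_dict(load_yaml(path))


def load_parameters(path) -> ModelParameters:
    try:
        return ModelParameters.from_dict(load_yaml(path))
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def load_geometry(data: dict | str | Path) -> PondGeometry:
    if not isinstance(data, dict):
        data = load_yaml(data)
    allowed = {"length", "width", "depth"}
    unknown = set(data) - allowed
    if unknown:
        raise SchemaError(f"unknown geometry keys: {sorted(unknown)}")
    return PondGeometry(**data)
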