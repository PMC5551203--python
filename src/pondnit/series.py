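"""Time-series containers: environmental forcing and effluent observations.

Both containers hold plain numpy arrays with strictly increasing times and
convert losslessly to/from pandas DataFrames using the package's CSV column
schemas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ForcingSeries", "ObservationSeries", "FORCING_COLUMNS", "OBS_COLUMNS"]

FORCING_COLUMNS = (
    "time_d",
    "temp_c",
    "ph",
    "do_mgl",
    "in_on_mgl",
    "in_nh3_mgl",
    "in_no3_mgl",
    "q_m3d",
)

OBS_COLUMNS = ("time_d", "on_mgl", "nh3_mgl", "no3_mgl")

STATE_VARIABLES = ("ON", "NH3", "NO3")


def _check_times(times: np.ndarray, minimum: int = 2) -> None:
    if times.size < minimum:
        raise ValueError(f"need at least {minimum} records, got {times.size}")
    if not np.all(np.isfinite(times)):
        raise ValueError("times must be finite")
    d = np.diff(times)
    if np.any(d <= 0):
        row = int(np.nonzero(d <= 0)[0][0]) + 1
        raise ValueError(f"times must be strictly increasing (violation at row {row})")


@dataclass(frozen=True)
class ForcingSeries:
    """Environmental and influent drivers of the pond over time.

    Attributes are aligned 1-d arrays: ``times`` (days), water temperature
    (degC), pH, dissolved oxygen (mg/L), influent ON/NH3/NO3 concentrations
    (mg/L) and inflow ``q`` (m^3/d).  Values between records are obtained by
    piecewise-linear interpolation.
    """

    times: np.ndarray
    temp: np.ndarray
    ph: np.ndarray
    do: np.ndarray
    in_on: np.ndarray
    in_nh3: np.ndarray
    in_no3: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("times", "temp", "ph", "do", "in_on", "in_nh3", "in_no3", "q"):
            a = np.ascontiguousarray(getattr(self, name), dtype=float)
            arrays[name] = a
            object.__setattr__(self, name, a)
        _check_times(arrays["times"])
        n = arrays["times"].size
        for name, a in arrays.items():
            if a.shape != (n,):
                raise ValueError(f"column {name} has length {a.size}, expected {n}")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"column {name} contains non-finite values")
        for name in ("do", "in_on", "in_nh3", "in_no3", "q"):
            if np.any(arrays[name] < 0):
                raise ValueError(f"column {name} must be non-negative")
        if np.any(arrays["ph"] < 0) or np.any(arrays["ph"] > 14):
            raise ValueError("pH must lie in [0, 14]")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def __len__(self) -> int:
        return self.times.size

    def interp(self, t):
        """Piecewise-linear interpolation of all channels at time(s) ``t``.

        Raises for times outside the recorded span (no extrapolation).
        """
        t = np.asarray(t, dtype=float)
        lo, hi = self.span
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(f"time {t} outside forcing span [{lo}, {hi}]")
        out = {
            name: np.interp(t, self.times, getattr(self, name))
            for name in ("temp", "ph", "do", "in_on", "in_nh3", "in_no3", "q")
        }
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_d": self.times,
                "temp_c": self.temp,
                "ph": self.ph,
                "do_mgl": self.do,
                "in_on_mgl": self.in_on,
                "in_nh3_mgl": self.in_nh3,
                "in_no3_mgl": self.in_no3,
                "q_m3d": self.q,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ForcingSeries":
        missing = set(FORCING_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"forcing table missing columns: {sorted(missing)}")
        return cls(
            times=df["time_d"].to_numpy(),
            temp=df["temp_c"].to_numpy(),
            ph=df["ph"].to_numpy(),
            do=df["do_mgl"].to_numpy(),
            in_on=df["in_on_mgl"].to_numpy(),
            in_nh3=df["in_nh3_mgl"].to_numpy(),
            in_no3=df["in_no3_mgl"].to_numpy(),
            q=df["q_m3d"].to_numpy(),
        )

    @classmethod
    def constant(
        cls,
        duration: float,
        temp: float,
        ph: float,
        do: float,
        influent: tuple[float, float, float],
        q: float,
        step: float = 1.0,
    ) -> "ForcingSeries":
        """Constant forcing over ``[0, duration]`` — convenient for tests."""
        t = np.arange(0.0, duration + 0.5 * step, step)
        ones = np.ones_like(t)
        return cls(
            times=t,
            temp=temp * ones,
            ph=ph * ones,
            do=do * ones,
            in_on=influent[0] * ones,
            in_nh3=influent[1] * ones,
            in_no3=influent[2] * ones,
            q=q * ones,
        )


@dataclass(frozen=True)
class ObservationSeries:
    """Weekly effluent concentration observations (mg/L) at sample times (days)."""

    times: np.ndarray
    values: np.ndarray  # shape (n, 3): ON, NH3, NO3

    def __post_init__(self) -> None:
        t = np.ascontiguousarray(self.times, dtype=float)
        v = np.ascontiguousarray(self.values, dtype=float)
        _check_times(t, minimum=2)
        if v.shape != (t.size, 3):
            raise ValueError(f"values must have shape ({t.size}, 3), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("observations contain non-finite values")
        if np.any(v < 0):
            raise ValueError("observed concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    @property
    def ON(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def NH3(self) -> np.ndarray:
        return self.values[:, 1]

    @property
    def NO3(self) -> np.ndarray:
        return self.values[:, 2]

    def window(self, t_start: float = -np.inf, t_end: float = np.inf) -> "ObservationSeries":
        """Sub-series with ``t_start < t <= t_end``."""
        mask = (self.times > t_start) & (self.times <= t_end)
        if mask.sum() < 2:
            raise ValueError("window contains fewer than 2 observations")
        return ObservationSeries(times=self.times[mask], values=self.values[mask])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_d": self.times,
                "on_mgl": self.values[:, 0],
                "nh3_mgl": self.values[:, 1],
                "no3_mgl": self.values[:, 2],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ObservationSeries":
        missing = set(OBS_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")
        return cls(
            times=df["time_d"].to_numpy(),
            values=np.column_stack(
                [df["on_mgl"].to_numpy(), df["nh3_mgl"].to_numpy(), df["no3_mgl"].to_numpy()]
            ),
        )
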