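"""Parameter, geometry and environment containers for the pond nitrogen model.

The model tracks three nitrogen pools (organic N, ammonia N, nitrate N) in a
completely mixed pond.  Nine kinetic constants are treated as calibratable;
the mineralization coefficient and the ammonia/nitrate uptake preference
factors are fixed structural constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "PondGeometry",
    "FlowRegime",
    "EnvState",
    "ModelParameters",
    "ParameterBounds",
    "FREE_PARAMETERS",
    "CALIBRATED",
    "LITERATURE_BOUNDS",
]

#: Names of the nine calibratable kinetic constants, in canonical order.
FREE_PARAMETERS = (
    "theta",
    "Rs",
    "K1",
    "K2",
    "K3",
    "R20",
    "Yn",
    "mun",
    "mumax20",
)


@dataclass(frozen=True)
class PondGeometry:
    """Rectangular pond geometry in meters; volume is derived."""

    length: float = 20.5
    width: float = 1.2
    depth: float = 0.80

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"pond {f.name} must be a positive finite number, got {v!r}")

    @property
    def volume(self) -> float:
        """Pond volume in cubic meters."""
        return self.length * self.width * self.depth


@dataclass(frozen=True)
class FlowRegime:
    """Influent (Qi) and effluent (Qe) flow rates in m^3/day."""

    inflow: float
    outflow: float

    def __post_init__(self) -> None:
        if self.inflow < 0 or self.outflow < 0:
            raise ValueError("flow rates must be non-negative")

    @classmethod
    def from_hrt(cls, geometry: PondGeometry, hrt_days: float) -> "FlowRegime":
        """Balanced inflow/outflow giving the requested hydraulic retention time."""
        if hrt_days <= 0:
            raise ValueError("hydraulic retention time must be positive")
        q = geometry.volume / hrt_days
        return cls(inflow=q, outflow=q)

    def hrt(self, volume: float) -> float:
        """Hydraulic retention time (days) = volume / inflow."""
        if self.inflow <= 0:
            raise ValueError("HRT undefined for zero inflow")
        return volume / self.inflow


@dataclass(frozen=True)
class EnvState:
    """Instantaneous environmental drivers: temperature (degC), pH, DO (mg/L)."""

    T: float
    pH: float
    DO: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.T, self.pH, self.DO))):
            raise ValueError("environmental state must be finite")
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"pH must be in [0, 14], got {self.pH}")
        if self.DO < 0:
            raise ValueError("dissolved oxygen must be non-negative")


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants of the nitrogen cycle model.

    The nine free constants (see :data:`FREE_PARAMETERS`) default to the
    calibrated values for the tropical pilot pond the model was developed
    for.  ``p1``/``p2`` partition microbial N uptake between ammonia and
    nitrate (microbes prefer ammonia strongly, so p1 >> p2); ``kmin`` is the
    temperature-linear mineralization coefficient.
    """

    theta: float = 1.01       # Arrhenius temperature-correction base (-)
    Rs: float = 0.050         # organic-N sedimentation constant (1/d)
    K1: float = 1.26          # Nitrosomonas half-saturation for DO (mg/L)
    K2: float = 16.20         # ammonium half-saturation for uptake (mg/L)
    K3: float = 2.0           # nitrate half-saturation for uptake (mg/L)
    R20: float = 0.26         # denitrification constant at 20 degC (1/d)
    Yn: float = 0.163         # Nitrosomonas yield (mg biomass / mg N)
    mun: float = 0.009        # Nitrosomonas growth rate (1/d)
    mumax20: float = 0.13     # max microbial growth rate at 20 degC (1/d)
    p1: float = 0.9           # ammonia uptake preference factor (-)
    p2: float = 0.1           # nitrate uptake preference factor (-)
    kmin: float = 0.002       # mineralization coefficient (1/(degC d))

    def __post_init__(self) -> None:
        # divisors and exponent bases must be strictly positive; pure rate
        # constants may be zero (e.g. reaction-free CSTR limit)
        for name in ("theta", "K1", "K2", "K3", "Yn", "p1"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {name} must be positive and finite, got {v!r}")
        for name in ("Rs", "R20", "mun", "mumax20", "kmin", "p2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"parameter {name} must be non-negative and finite, got {v!r}")
        if abs(self.p1 + self.p2 - 1.0) > 1e-9:
            raise ValueError("preference factors must satisfy p1 + p2 == 1")

    def free_values(self) -> np.ndarray:
        """The nine calibratable constants as an array in canonical order."""
        return np.array([getattr(self, n) for n in FREE_PARAMETERS], dtype=float)

    def with_free_values(self, values: np.ndarray) -> "ModelParameters":
        """Return a copy with the nine free constants replaced."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(FREE_PARAMETERS),):
            raise ValueError(f"expected {len(FREE_PARAMETERS)} values, got shape {values.shape}")
        return replace(self, **dict(zip(FREE_PARAMETERS, values.tolist())))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


#: Calibrated constants for the study pond (also the class defaults).
CALIBRATED = ModelParameters()

#: Published literature ranges for the free constants; single published
#: values are widened by +/-50% to give a usable search interval.
LITERATURE_BOUNDS = {
    "theta": (1.01, 1.09),
    "Rs": (0.0075, 0.0225),      # 0.015 +/- 50%
    "K1": (0.13, 0.15),
    "K2": (9.0, 27.0),           # 18.0 +/- 50%
    "K3": (1.0, 3.0),            # 2.0 +/- 50%
    "R20": (1e-4, 1.0),          # "0.0 to 1.0", floored away from zero
    "Yn": (0.065, 0.195),        # 0.13 +/- 50%
    "mun": (0.004, 0.012),       # 0.008 +/- 50%
    "mumax20": (0.1, 0.77),
}


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds on the nine free kinetic constants.

    Built either from published literature ranges or as a symmetric
    fractional window around a center vector (the +/-10% window used for
    the calibration and uncertainty stages).
    """

    lower: np.ndarray = field()
    upper: np.ndarray = field()

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        if lo.shape != (len(FREE_PARAMETERS),) or up.shape != lo.shape:
            raise ValueError("bounds must have one (lower, upper) pair per free parameter")
        if not np.all(lo < up):
            bad = [FREE_PARAMETERS[i] for i in np.nonzero(~(lo < up))[0]]
            raise ValueError(f"lower bound must be strictly below upper for {bad}")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @classmethod
    def around(cls, center: ModelParameters, fraction: float = 0.10) -> "ParameterBounds":
        """Symmetric +/-``fraction`` window around ``center``'s free values."""
        if not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        c = center.free_values()
        return cls(lower=c * (1 - fraction), upper=c * (1 + fraction))

    @classmethod
    def from_literature(cls) -> "ParameterBounds":
        lo = np.array([LITERATURE_BOUNDS[n][0] for n in FREE_PARAMETERS])
        up = np.array([LITERATURE_BOUNDS[n][1] for n in FREE_PARAMETERS])
        return cls(lower=lo, upper=up)

    def contains(self, values: np.ndarray) -> bool:
        v = np.asarray(values, dtype=float)
        return bool(np.all(v >= self.lower) & np.all(v <= self.upper))

    def clip(self, values: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(values, dtype=float), self.lower, self.upper)

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def to_dict(self) -> dict:
        return {
            n: [float(self.lower[i]), float(self.upper[i])]
            for i, n in enumerate(FREE_PARAMETERS)
        }
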