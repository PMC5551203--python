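"""Reaction rate laws of the pond nitrogen cycle.

Seven volumetric rates (all mg/L/d) link the three nitrogen pools:

* mineralization  rm = kmin * T * ON           (organic N -> ammonia)
* nitrification   rn = (mun/Yn) * Monod(NH3; Kn) * Monod(DO; K1) * CT * CpH
* sedimentation   rs = Rs * ON                 (permanent organic-N loss)
* denitrification rd = R20 * theta^(T-20) * NO3
* volatilization  rv = NH3 * 0.0566 * exp(0.13 (T-20))
                       / (d * (1 + 10^(10.5 - 0.03 T - pH)))
* uptake of NH3   r1 = mumax20 * theta^(T-20) * Monod(NH3; K2) * ON * p1
* uptake of NO3   r2 = mumax20 * theta^(T-20) * Monod(NO3; K3) * ON * p2

Nitrification carries no explicit Nitrosomonas biomass state: the prefactor
mun/Yn is taken directly as a volumetric substrate-utilization rate.  The
nitrification environmental factors follow Downing's model: Kn grows
exponentially with temperature, CT references 15 degC, and CpH falls
linearly below pH 7.2 (floored at zero near pH 6, where the linear form
would go negative).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .parameters import EnvState, ModelParameters

__all__ = ["RateVector", "nitrification_factors", "reaction_rates"]


class RateVector(NamedTuple):
    """The seven reaction rates, each in mg/L/d."""

    rm: float
    rn: float
    rs: float
    rd: float
    rv: float
    r1: float
    r2: float


def nitrification_factors(T, pH):
    """Downing-model environmental factors for nitrification.

    Parameters
    ----------
    T : float or ndarray
        Water temperature in degC.
    pH : float or ndarray
        Water pH (0-14).

    Returns
    -------
    Kn : ammonia half-saturation constant, mg/L; ``10^(0.051 T - 1.58)``.
    CT : temperature correction, ``exp(0.098 (T - 15))`` (unity at 15 degC).
    CpH : pH growth-inhibition factor; unity at pH >= 7.2, decreasing
        linearly below and floored at 0.
    """
    T = np.asarray(T, dtype=float)
    pH = np.asarray(pH, dtype=float)
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(pH))):
        raise ValueError("temperature and pH must be finite")
    if np.any(pH < 0) or np.any(pH > 14):
        raise ValueError("pH must be in [0, 14]")
    Kn, CT, CpH = _factors_raw(T, pH)
    if Kn.ndim == 0:
        return float(Kn), float(CT), float(CpH)
    return Kn, CT, CpH


def _factors_raw(T, pH):
    T = np.asarray(T, dtype=float)
    pH = np.asarray(pH, dtype=float)
    Kn = 10.0 ** (0.051 * T - 1.58)
    CT = np.exp(0.098 * (T - 15.0))
    CpH = np.where(pH >= 7.2, 1.0, np.maximum(0.0, 1.0 - 0.833 * (7.2 - pH)))
    return Kn, CT, CpH


def reaction_rates(state, env: EnvState, params: ModelParameters, depth: float) -> RateVector:
    """Evaluate the seven reaction rates at a pond state.

    Parameters
    ----------
    state : sequence of (ON, NH3, NO3)
        Pond concentrations in mg/L; scalars or aligned arrays.
    env : EnvState
        Temperature, pH and dissolved oxygen.
    params : ModelParameters
    depth : float
        Pond depth in meters (enters the volatilization rate).

    Returns
    -------
    RateVector
        All rates clamped at >= 0.
    """
    ON, NH3, NO3 = (np.asarray(c, dtype=float) for c in state)
    if np.any(ON < 0) or np.any(NH3 < 0) or np.any(NO3 < 0):
        raise ValueError("concentrations must be non-negative")
    if depth <= 0:
        raise ValueError("pond depth must be positive")

    rates = rates_arrays(ON, NH3, NO3, env.T, env.pH, env.DO, params, depth)
    if np.asarray(rates[0]).ndim == 0:
        return RateVector(*(float(r) for r in rates))
    return rates


def rates_arrays(ON, NH3, NO3, T, pH, DO, params: ModelParameters, depth: float) -> RateVector:
    """Vectorized rate evaluation over aligned arrays; no input validation."""
    T = np.asarray(T, dtype=float)
    Kn, CT, CpH = _factors_raw(T, pH)
    arrh = params.theta ** (T - 20.0)

    rm = params.kmin * T * ON
    rn = (params.mun / params.Yn) * _monod(NH3, Kn) * _monod(DO, params.K1) * CT * CpH
    rs = params.Rs * ON
    rd = params.R20 * arrh * NO3
    rv = (
        NH3 * 0.0566 * np.exp(0.13 * (T - 20.0))
        / (depth * (1.0 + 10.0 ** (10.5 - 0.03 * T - pH)))
    )
    r1 = params.mumax20 * arrh * _monod(NH3, params.K2) * ON * params.p1
    r2 = params.mumax20 * arrh * _monod(NO3, params.K3) * ON * params.p2

    return RateVector(*(np.maximum(r, 0.0) for r in (rm, rn, rs, rd, rv, r1, r2)))


def rates_scalar(ON, NH3, NO3, T, pH, DO, params: ModelParameters, depth: float):
    """Scalar rate evaluation in plain Python floats.

    Semantically identical to :func:`reaction_rates`; used inside the ODE
    right-hand side where per-call numpy overhead dominates.  A unit test
    pins the two implementations against each other.
    """
    import math

    Kn = 10.0 ** (0.051 * T - 1.58)
    CT = math.exp(0.098 * (T - 15.0))
    CpH = 1.0 if pH >= 7.2 else max(0.0, 1.0 - 0.833 * (7.2 - pH))
    arrh = params.theta ** (T - 20.0)

    rm = params.kmin * T * ON
    rn = (
        (params.mun / params.Yn)
        * (NH3 / (Kn + NH3) if Kn + NH3 > 0 else 0.0)
        * (DO / (params.K1 + DO))
        * CT
        * CpH
    )
    rs = params.Rs * ON
    rd = params.R20 * arrh * NO3
    rv = (
        NH3 * 0.0566 * math.exp(0.13 * (T - 20.0))
        / (depth * (1.0 + 10.0 ** (10.5 - 0.03 * T - pH)))
    )
    r1 = params.mumax20 * arrh * (NH3 / (params.K2 + NH3)) * ON * params.p1
    r2 = params.mumax20 * arrh * (NO3 / (params.K3 + NO3)) * ON * params.p2
    return (
        rm if rm > 0 else 0.0,
        rn if rn > 0 else 0.0,
        rs if rs > 0 else 0.0,
        rd if rd > 0 else 0.0,
        rv if rv > 0 else 0.0,
        r1 if r1 > 0 else 0.0,
        r2 if r2 > 0 else 0.0,
    )


def _monod(substrate, half_sat):
    """Monod saturation term S / (K + S); 0 when S == K == 0."""
    denom = half_sat + substrate
    return np.divide(
        substrate, denom, out=np.zeros_like(np.asarray(substrate, dtype=float)), where=denom > 0
    )
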