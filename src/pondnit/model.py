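"""Completely mixed pond nitrogen model: mass balances, integration, fitting.

The pond is treated as a single continuous stirred tank reactor (CSTR) with
three state variables — organic N, ammonia N and nitrate N (mg/L).  Each
pool is driven by hydraulic exchange (influent load in, washout out) and by
the seven reaction rates of :mod:`pondnit.kinetics`:

    dON/dt  = (Qi/V) ONin  - (Qe/V) ON  - rm - rs + r1 + r2
    dNH3/dt = (Qi/V) NH3in - (Qe/V) NH3 - r1 + rm - rv - rn
    dNO3/dt = (Qi/V) NO3in - (Qe/V) NO3 + rn - r2 - rd

Denitrification is a nitrate sink by default; the ``literal_eq4_sign``
flag flips it to a source for comparison with formulations that write +rd.

:class:`PondModel` bundles forcing, geometry and observations and exposes
``simulate`` and ``fit`` (controlled random search + adaptive Metropolis),
returning a :class:`~pondnit.results.PondFitResults`.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import calibration as cal
from .exceptions import IntegrationError, UndefinedMetricError
from .kinetics import rates_arrays, rates_scalar
from .parameters import (
    FREE_PARAMETERS,
    FlowRegime,
    ModelParameters,
    ParameterBounds,
    PondGeometry,
)
from .series import STATE_VARIABLES, ForcingSeries, ObservationSeries

__all__ = [
    "SimulationResult",
    "derivatives",
    "simulate",
    "nitrogen_budget",
    "PondModel",
]

RATE_NAMES = ("rm", "rn", "rs", "rd", "rv", "r1", "r2")


@dataclass
class SimulationResult:
    """State trajectory with per-pathway rate breakdown.

    ``pathway_totals`` holds time-integrated removals in mg/L-equivalents:
    sedimentation, volatilization, denitrification and the hydraulic export
    (mass leaving with the effluent, per pond volume).
    """

    times: np.ndarray            # (n,) days
    states: np.ndarray           # (n, 3) ON, NH3, NO3 in mg/L
    rates: np.ndarray            # (n, 7) rm, rn, rs, rd, rv, r1, r2 in mg/L/d
    pathway_totals: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def ON(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def NH3(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def NO3(self) -> np.ndarray:
        return self.states[:, 2]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_d": self.times,
                "on_mgl": self.states[:, 0],
                "nh3_mgl": self.states[:, 1],
                "no3_mgl": self.states[:, 2],
            }
        )
        for j, name in enumerate(RATE_NAMES):
            df[name] = self.rates[:, j]
        return df


def derivatives(
    t: float,
    state,
    forcing: ForcingSeries,
    params: ModelParameters,
    geometry: PondGeometry,
    flow: FlowRegime | None = None,
    literal_eq4_sign: bool = False,
) -> np.ndarray:
    """Right-hand side of the CSTR mass balances at a single time.

    Raises outside the forcing span (no extrapolation) and for negative
    states.  This is the reference implementation; the integrator uses an
    equivalent fast scalar closure.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError("state concentrations must be non-negative")
    f = forcing.interp(t)  # raises outside span
    qi = flow.inflow if flow is not None else float(f["q"])
    qe = flow.outflow if flow is not None else float(f["q"])
    V = geometry.volume
    ON, NH3, NO3 = state
    rm, rn, rs, rd, rv, r1, r2 = rates_scalar(
        ON, NH3, NO3, float(f["temp"]), float(f["ph"]), float(f["do"]), params, geometry.depth
    )
    sign = 1.0 if literal_eq4_sign else -1.0
    return np.array(
        [
            (qi / V) * float(f["in_on"]) - (qe / V) * ON - rm - rs + r1 + r2,
            (qi / V) * float(f["in_nh3"]) - (qe / V) * NH3 - r1 + rm - rv - rn,
            (qi / V) * float(f["in_no3"]) - (qe / V) * NO3 + rn - r2 + sign * rd,
        ]
    )


def _make_rhs(
    forcing: ForcingSeries,
    params: ModelParameters,
    geometry: PondGeometry,
    flow: FlowRegime | None,
    literal_eq4_sign: bool,
):
    """Build a fast scalar RHS closure (plain-float math, bisect interpolation)."""
    times = forcing.times.tolist()
    n = len(times)
    rows = list(
        zip(
            forcing.temp.tolist(),
            forcing.ph.tolist(),
            forcing.do.tolist(),
            forcing.in_on.tolist(),
            forcing.in_nh3.tolist(),
            forcing.in_no3.tolist(),
            forcing.q.tolist(),
        )
    )
    V = geometry.volume
    depth = geometry.depth
    sign = 1.0 if literal_eq4_sign else -1.0
    qi_fixed = flow.inflow if flow is not None else None
    qe_fixed = flow.outflow if flow is not None else None

    def rhs(t, y):
        ON = y[0] if y[0] > 0.0 else 0.0
        NH3 = y[1] if y[1] > 0.0 else 0.0
        NO3 = y[2] if y[2] > 0.0 else 0.0

        i = bisect.bisect_right(times, t)
        if i <= 0:
            i = 1
        elif i >= n:
            i = n - 1
        t0 = times[i - 1]
        w = (t - t0) / (times[i] - t0)
        a = rows[i - 1]
        b = rows[i]
        T = a[0] + w * (b[0] - a[0])
        pH = a[1] + w * (b[1] - a[1])
        DO = a[2] + w * (b[2] - a[2])
        on_in = a[3] + w * (b[3] - a[3])
        nh3_in = a[4] + w * (b[4] - a[4])
        no3_in = a[5] + w * (b[5] - a[5])
        q = a[6] + w * (b[6] - a[6])
        qi = qi_fixed if qi_fixed is not None else q
        qe = qe_fixed if qe_fixed is not None else q

        rm, rn, rs, rd, rv, r1, r2 = rates_scalar(ON, NH3, NO3, T, pH, DO, params, depth)
        return (
            (qi / V) * on_in - (qe / V) * ON - rm - rs + r1 + r2,
            (qi / V) * nh3_in - (qe / V) * NH3 - r1 + rm - rv - rn,
            (qi / V) * no3_in - (qe / V) * NO3 + rn - r2 + sign * rd,
        )

    return rhs


def simulate(
    params: ModelParameters,
    forcing: ForcingSeries,
    geometry: PondGeometry,
    flow: FlowRegime | None = None,
    init=(0.0, 0.0, 0.0),
    output_times=None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    literal_eq4_sign: bool = False,
    record_rates: bool = True,
) -> SimulationResult:
    """Integrate the pond model over the forcing span.

    Integration starts at the first forcing time with state ``init``; the
    trajectory is reported at ``output_times`` (default: daily).  Uses the
    stiff-capable adaptive LSODA solver; the state is clipped at zero
    inside the right-hand side, so concentrations stay non-negative.
    """
    t_lo, t_hi = forcing.span
    if output_times is None:
        output_times = np.arange(np.ceil(t_lo), np.floor(t_hi) + 0.5)
    output_times = np.asarray(output_times, dtype=float)
    if output_times.size < 1:
        raise ValueError("need at least one output time")
    if np.any(np.diff(output_times) <= 0):
        raise ValueError("output_times must be strictly increasing")
    if output_times[0] < t_lo or output_times[-1] > t_hi:
        raise ValueError(
            f"output_times [{output_times[0]}, {output_times[-1]}] outside forcing span [{t_lo}, {t_hi}]"
        )
    init = np.asarray(init, dtype=float)
    if init.shape != (3,) or np.any(init < 0):
        raise ValueError("init must be three non-negative concentrations")

    rhs = _make_rhs(forcing, params, geometry, flow, literal_eq4_sign)
    sol = solve_ivp(
        rhs,
        (t_lo, float(output_times[-1])),
        init,
        method="LSODA",
        t_eval=output_times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else t_lo
        raise IntegrationError(f"ODE integration failed near t={t_fail:.3f} d: {sol.message}", t_fail)

    states = np.clip(sol.y.T, 0.0, None)
    result = SimulationResult(
        times=output_times,
        states=states,
        rates=np.empty((output_times.size, 0)),
        meta={
            "volume": geometry.volume,
            "depth": geometry.depth,
            "literal_eq4_sign": literal_eq4_sign,
        },
    )
    if not record_rates:
        return result

    f = forcing.interp(output_times)
    rates = rates_arrays(
        states[:, 0], states[:, 1], states[:, 2],
        f["temp"], f["ph"], f["do"], params, geometry.depth,
    )
    result.rates = np.column_stack(rates)

    qi = np.full_like(output_times, flow.inflow) if flow is not None else f["q"]
    qe = np.full_like(output_times, flow.outflow) if flow is not None else f["q"]
    V = geometry.volume
    c_tot = states.sum(axis=1)
    cin_tot = f["in_on"] + f["in_nh3"] + f["in_no3"]
    result.pathway_totals = {
        "sedimentation": float(np.trapezoid(rates.rs, output_times)),
        "volatilization": float(np.trapezoid(rates.rv, output_times)),
        "denitrification": float(np.trapezoid(rates.rd, output_times)),
        "hydraulic_export": float(np.trapezoid(qe / V * c_tot, output_times)),
    }
    result.meta.update(
        {
            "hydraulic_inflow": float(np.trapezoid(qi / V * cin_tot, output_times)),
            "mean_q": float(np.mean(qi)),
            "storage_change": float(c_tot[-1] - c_tot[0]),
        }
    )
    return result


def nitrogen_budget(result: SimulationResult) -> dict:
    """Fractions of removed nitrogen attributed to each loss pathway.

    Total removal is influent load minus effluent load minus storage change
    (all per pond volume); by mass conservation it equals the sum of the
    sedimentation, volatilization and denitrification integrals up to
    integration error.  Requires a run spanning at least one hydraulic
    retention time and recorded rates.
    """
    pt = result.pathway_totals
    if not pt:
        raise ValueError("simulation was run without rate recording")
    span = float(result.times[-1] - result.times[0])
    hrt = result.meta["volume"] / result.meta["mean_q"]
    if span < hrt:
        raise ValueError(f"budget needs a span >= 1 HRT ({hrt:.2f} d), got {span:.2f} d")
    removed = (
        result.meta["hydraulic_inflow"]
        - pt["hydraulic_export"]
        - result.meta["storage_change"]
    )
    if removed <= 0:
        raise UndefinedMetricError("no net nitrogen removal; pathway fractions undefined")
    return {
        "sedimentation": pt["sedimentation"] / removed,
        "volatilization": pt["volatilization"] / removed,
        "denitrification": pt["denitrification"] / removed,
    }


class PondModel:
    """A pond nitrogen model bound to forcing, geometry and observations.

    Parameters
    ----------
    forcing : ForcingSeries
        Environmental and influent drivers.
    observations : ObservationSeries, optional
        Weekly effluent concentrations; required for fitting.
    geometry : PondGeometry
        Defaults to the 20.5 x 1.2 x 0.80 m pilot pond.
    flow : FlowRegime, optional
        Constant inflow/outflow override; by default the forcing's ``q``
        column drives balanced inflow and outflow.
    init : sequence of 3 floats, optional
        Initial (ON, NH3, NO3); defaults to the influent concentrations at
        the first forcing time.
    params : ModelParameters, optional
        Center/default parameter vector (also the default bounds center).
    calibration_end : float, optional
        Time (days) splitting observations into calibration and validation
        windows; defaults to the midpoint of the observation span.
    """

    def __init__(
        self,
        forcing: ForcingSeries,
        observations: ObservationSeries | None = None,
        geometry: PondGeometry | None = None,
        flow: FlowRegime | None = None,
        init=None,
        params: ModelParameters | None = None,
        calibration_end: float | None = None,
        literal_eq4_sign: bool = False,
        rtol: float = 1e-6,
        atol: float = 1e-9,
    ):
        self.forcing = forcing
        self.observations = observations
        self.geometry = geometry if geometry is not None else PondGeometry()
        self.flow = flow
        self.params = params if params is not None else ModelParameters()
        if init is None:
            init = (forcing.in_on[0], forcing.in_nh3[0], forcing.in_no3[0])
        self.init = np.asarray(init, dtype=float)
        if calibration_end is None and observations is not None:
            t = observations.times
            calibration_end = float(t[0] + (t[-1] - t[0]) / 2.0)
        self.calibration_end = calibration_end
        self.literal_eq4_sign = literal_eq4_sign
        self.rtol = rtol
        self.atol = atol

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_dataframes(cls, forcing_df: pd.DataFrame, obs_df: pd.DataFrame | None = None, **kw):
        forcing = ForcingSeries.from_dataframe(forcing_df)
        obs = ObservationSeries.from_dataframe(obs_df) if obs_df is not None else None
        return cls(forcing, obs, **kw)

    @classmethod
    def from_csv(cls, forcing_path, obs_path=None, **kw):
        from .io import read_forcing_csv, read_observations_csv

        forcing = read_forcing_csv(forcing_path)
        obs = read_observations_csv(obs_path) if obs_path is not None else None
        return cls(forcing, obs, **kw)

    # ---------------------------------------------------------- simulation
    def simulate(self, params: ModelParameters | None = None, output_times=None, **kw) -> SimulationResult:
        """Run the model; see :func:`simulate`."""
        return simulate(
            params if params is not None else self.params,
            self.forcing,
            self.geometry,
            flow=self.flow,
            init=self.init,
            output_times=output_times,
            rtol=self.rtol,
            atol=self.atol,
            literal_eq4_sign=self.literal_eq4_sign,
            **kw,
        )

    def predict(self, params: ModelParameters, times) -> np.ndarray:
        """States (n, 3) at the requested times; no rate recording."""
        return self.simulate(params, output_times=times, record_rates=False).states

    # ------------------------------------------------------------- metrics
    def _window(self, which: str) -> ObservationSeries:
        if self.observations is None:
            raise ValueError("model has no observations")
        if which == "all":
            return self.observations
        if self.calibration_end is None:
            raise ValueError("no calibration/validation split defined")
        if which == "calibration":
            return self.observations.window(-np.inf, self.calibration_end)
        if which == "validation":
            return self.observations.window(self.calibration_end, np.inf)
        raise ValueError(f"unknown window {which!r}")

    def per_variable_nse(self, params: ModelParameters, window: str = "calibration") -> dict:
        obs = self._window(window)
        sim = self.predict(params, obs.times)
        return {
            v: cal.nse(obs.values[:, j], sim[:, j]) for j, v in enumerate(STATE_VARIABLES)
        }

    def per_variable_r(self, params: ModelParameters, window: str = "calibration") -> dict:
        obs = self._window(window)
        sim = self.predict(params, obs.times)
        return {
            v: cal.pearson_r(obs.values[:, j], sim[:, j]) for j, v in enumerate(STATE_VARIABLES)
        }

    def objective(self, free_values, weights=None) -> float:
        """Mean per-variable NSE on the calibration window; -inf on failure."""
        nse_v = self._eval_free(np.asarray(free_values, dtype=float))
        if nse_v is None:
            return -np.inf
        return cal.combined_objective(nse_v, weights)

    def _calibration_arrays(self):
        obs = self._window("calibration")
        denom = np.sum((obs.values - obs.values.mean(axis=0)) ** 2, axis=0)
        if np.any(denom == 0):
            raise UndefinedMetricError("an observed variable has zero variance")
        return obs.times, obs.values, denom

    def _eval_free(self, x: np.ndarray, cached=None):
        """Per-variable calibration NSEs for a free-parameter vector, or None."""
        times, values, denom = cached if cached is not None else self._calibration_arrays()
        try:
            params = self.params.with_free_values(x)
            sim = self.predict(params, times)
        except (IntegrationError, ValueError):
            return None
        ssr = np.sum((values - sim) ** 2, axis=0)
        return 1.0 - ssr / denom

    # ----------------------------------------------------------------- fit
    def sample_posterior(
        self,
        start=None,
        bounds: ParameterBounds | None = None,
        n_mcmc: int = 5000,
        seed: int | None = 0,
        burn_frac: float = 0.2,
        weights=None,
    ):
        """Adaptive Metropolis sampling of the parameter posterior.

        The Gaussian error model's per-variable variances are frozen from
        the residuals at the starting point.  Each chain evaluation also
        records the calibration objective and per-variable NSEs, which the
        GLUE stage reuses.
        """
        if bounds is None:
            bounds = ParameterBounds.around(self.params, 0.10)
        start = np.asarray(
            start if start is not None else self.params.free_values(), dtype=float
        )
        cached = self._calibration_arrays()
        times, values, denom = cached

        sim0 = self.predict(self.params.with_free_values(start), times)
        sigma2 = np.maximum(np.mean((values - sim0) ** 2, axis=0), 1e-12)

        def log_prob(x):
            nse_v = self._eval_free(x, cached)
            if nse_v is None:
                return -np.inf
            ssr = (1.0 - nse_v) * denom
            lp = -0.5 * float(np.sum(ssr / sigma2))
            return lp, cal.combined_objective(nse_v, weights), nse_v

        return cal.mcmc_sample(
            log_prob,
            start,
            bounds.lower,
            bounds.upper,
            n_samples=n_mcmc,
            seed=seed,
            burn_frac=burn_frac,
            param_names=FREE_PARAMETERS,
        )

    def fit(
        self,
        bounds: ParameterBounds | None = None,
        n_pseudo: int = 500,
        n_mcmc: int = 5000,
        seed: int | None = 0,
        weights=None,
        burn_frac: float = 0.2,
    ):
        """Two-stage calibration: controlled random search, then MCMC.

        The random search (``n_pseudo`` objective evaluations) brings the
        parameters near the optimum; the adaptive Metropolis chain
        (``n_mcmc`` samples) then explores the posterior under a Gaussian
        error model whose per-variable variances are fixed from the
        residuals at the search optimum.  The reported best fit is the
        highest-objective point seen across both stages.
        """
        from .results import PondFitResults

        if bounds is None:
            bounds = ParameterBounds.around(self.params, 0.10)
        cached = self._calibration_arrays()
        times, values, denom = cached
        n_obs = len(times)

        def objective(x):
            nse_v = self._eval_free(x, cached)
            if nse_v is None:
                return -np.inf
            return cal.combined_objective(nse_v, weights)

        pseudo = cal.pseudo_search(
            objective, bounds.lower, bounds.upper, n_iter=n_pseudo, seed=seed
        )
        if not np.isfinite(pseudo.fun):
            raise IntegrationError("random search found no feasible simulation")

        chain = self.sample_posterior(
            start=pseudo.x,
            bounds=bounds,
            n_mcmc=n_mcmc,
            seed=None if seed is None else seed + 1,
            burn_frac=burn_frac,
            weights=weights,
        )

        i_best = chain.best_index()
        if chain.objective is not None and chain.objective[i_best] >= pseudo.fun:
            best_x = chain.samples[i_best]
            best_obj = float(chain.objective[i_best])
        else:
            best_x, best_obj = pseudo.x, pseudo.fun
        best_params = self.params.with_free_values(best_x)

        nse_tbl = pd.DataFrame(index=list(STATE_VARIABLES))
        r_tbl = pd.DataFrame(index=list(STATE_VARIABLES))
        for window in ("calibration", "validation"):
            try:
                nse_tbl[window] = pd.Series(self.per_variable_nse(best_params, window))
                r_tbl[window] = pd.Series(self.per_variable_r(best_params, window))
            except ValueError:
                pass  # no validation window defined

        return PondFitResults(
            model=self,
            params=best_params,
            objective_value=best_obj,
            nse=nse_tbl,
            r=r_tbl,
            pseudo=pseudo,
            chain=chain,
            bounds=bounds,
            seed=seed,
            n_obs_calibration=n_obs,
        )
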