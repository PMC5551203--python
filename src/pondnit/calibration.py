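"""Goodness-of-fit metrics and the two-stage calibration machinery.

Calibration maximizes the Nash-Sutcliffe efficiency (NSE), used both as the
objective and, in the GLUE stage, as the behavioral likelihood measure.  A
bounded controlled-random-search ("pseudo" random search, Price-style)
locates the vicinity of the optimum; an adaptive Metropolis chain then
samples the parameter posterior under a fixed Gaussian error model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, InitializationError, UndefinedMetricError

__all__ = [
    "nse",
    "pearson_r",
    "combined_objective",
    "pseudo_search",
    "PseudoSearchResult",
    "mcmc_sample",
    "ChainResult",
]


def nse(observed, simulated) -> float:
    """Nash-Sutcliffe efficiency: ``1 - sum(res^2) / sum((obs - mean)^2)``.

    1 is a perfect fit; 0 means no better than predicting the observed
    mean; negative values are worse than the mean benchmark.
    """
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape or obs.ndim != 1:
        raise ValueError("observed and simulated must be 1-d arrays of equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    denom = float(np.sum((obs - obs.mean()) ** 2))
    if denom == 0.0:
        raise UndefinedMetricError("NSE undefined: observed series has zero variance")
    return 1.0 - float(np.sum((obs - sim) ** 2)) / denom


def pearson_r(observed, simulated) -> float:
    """Product-moment correlation of two equal-length series."""
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape or obs.ndim != 1:
        raise ValueError("observed and simulated must be 1-d arrays of equal length")
    if obs.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(obs) == 0 or np.ptp(sim) == 0:
        raise UndefinedMetricError("correlation undefined for a constant series")
    return float(stats.pearsonr(obs, sim).statistic)


def combined_objective(per_variable_nse, weights=None) -> float:
    """Scalar calibration objective: weighted mean of per-variable NSEs.

    Non-finite inputs (failed simulations) collapse to ``-inf``.
    """
    v = np.asarray(per_variable_nse, dtype=float)
    if not np.all(np.isfinite(v)):
        return -np.inf
    if weights is None:
        return float(v.mean())
    w = np.asarray(weights, dtype=float)
    if w.shape != v.shape or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative, same length as NSE vector, not all zero")
    return float(np.sum(w * v) / w.sum())


@dataclass
class PseudoSearchResult:
    """Outcome of the controlled random search."""

    x: np.ndarray
    fun: float
    trace: np.ndarray  # best objective after each function evaluation
    n_eval: int
    seed: int | None = None


def pseudo_search(
    func: Callable[[np.ndarray], float],
    lower,
    upper,
    n_iter: int = 500,
    seed: int | None = None,
    n_pop: int | None = None,
) -> PseudoSearchResult:
    """Bounded controlled random search (Price) maximizing ``func``.

    A population of ``n_pop`` points (default 5 x dimension) is initialized
    uniformly in the box; each iteration reflects a random point through the
    centroid of a random simplex anchored at the current best point (the
    CRS2 refinement) and replaces the current worst population member when
    the trial improves on it.  ``n_iter`` counts total function evaluations
    including the initial population.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or lower.ndim != 1:
        raise ConfigurationError("lower/upper must be 1-d arrays of equal length")
    if not np.all(lower < upper):
        raise ConfigurationError("empty feasible region: lower must be < upper")
    d = lower.size
    if n_pop is None:
        n_pop = 5 * d
    if n_iter < n_pop:
        raise ConfigurationError(f"n_iter ({n_iter}) must be >= population size ({n_pop})")

    rng = np.random.default_rng(seed)
    pop = lower + rng.random((n_pop, d)) * (upper - lower)
    fvals = np.array([func(x) for x in pop], dtype=float)
    trace = list(np.maximum.accumulate(fvals))
    n_eval = n_pop

    best_x = pop[int(np.argmax(fvals))].copy()
    best_f = float(np.max(fvals))

    attempts = 0
    max_attempts = 200 * n_iter
    while n_eval < n_iter and attempts < max_attempts:
        attempts += 1
        # simplex anchored at the current best plus d random points; the
        # reflected pole may coincide with a centroid member, which yields
        # occasional contraction moves that refine the neighborhood of the
        # optimum (CRS2-style local concentration)
        i_best = int(np.argmax(fvals))
        others = rng.choice(n_pop, size=d, replace=False)
        if i_best in others:
            simplex = np.concatenate(([i_best], others[others != i_best]))
        else:
            simplex = np.concatenate(([i_best], others[: d - 1]))
        centroid = pop[simplex].mean(axis=0)
        trial = 2.0 * centroid - pop[others[-1]]
        if np.any(trial < lower) or np.any(trial > upper):
            continue
        f = func(trial)
        n_eval += 1
        worst = int(np.argmin(fvals))
        if f > fvals[worst]:
            pop[worst] = trial
            fvals[worst] = f
        if f > best_f:
            best_f = float(f)
            best_x = trial.copy()
        trace.append(best_f)

    return PseudoSearchResult(
        x=best_x, fun=best_f, trace=np.asarray(trace), n_eval=n_eval, seed=seed
    )


@dataclass
class ChainResult:
    """An adaptive-Metropolis chain with per-sample diagnostics.

    ``objective`` holds the mean-NSE calibration objective for each sample
    and ``aux`` the per-variable NSEs (when the target function supplies
    them), which the GLUE stage reuses without re-simulating.
    """

    samples: np.ndarray          # (n, d)
    logp: np.ndarray             # (n,)
    accepted: int
    burn_in: int
    seed: int | None = None
    param_names: tuple = ()
    objective: np.ndarray | None = None
    aux: np.ndarray | None = None  # (n, k) per-variable NSEs

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.logp = np.asarray(self.logp, dtype=float)
        if self.samples.ndim != 2 or self.logp.shape != (len(self.samples),):
            raise ValueError("inconsistent chain shapes")
        if not 0 <= self.burn_in < len(self.samples):
            raise ValueError("burn_in must index into the chain")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / len(self.samples)

    @property
    def posterior(self) -> np.ndarray:
        """Samples after burn-in."""
        return self.samples[self.burn_in:]

    def best_index(self) -> int:
        """Index of the highest-objective (or highest-logp) sample."""
        score = self.objective if self.objective is not None else self.logp
        return int(np.argmax(score))


def mcmc_sample(
    log_prob: Callable,
    x0,
    lower,
    upper,
    n_samples: int = 5000,
    seed: int | None = None,
    adapt_interval: int = 100,
    burn_frac: float = 0.2,
    initial_step_frac: float = 0.05,
    param_names: Sequence[str] = (),
) -> ChainResult:
    """Adaptive Metropolis sampling of ``log_prob`` within box bounds.

    ``log_prob`` may return a scalar log-density or a tuple
    ``(log_density, extras)``; extras are stacked into ``ChainResult.aux``
    (first extra interpreted as the calibration objective when it is a
    tuple ``(logp, objective, per_variable)``).  Proposals are Gaussian;
    the proposal covariance starts diagonal at ``initial_step_frac`` of the
    box span and is re-estimated from the chain history every
    ``adapt_interval`` steps with the standard 2.38^2/d scaling.
    Out-of-bounds proposals are rejected outright (uniform prior on the box).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    if np.any(x < lower) or np.any(x > upper):
        raise InitializationError("initial point outside bounds")

    rng = np.random.default_rng(seed)

    def evaluate(xv):
        out = log_prob(xv)
        if isinstance(out, tuple):
            lp, *extras = out
            obj = float(extras[0]) if len(extras) >= 1 else None
            aux = np.asarray(extras[1], dtype=float) if len(extras) >= 2 else None
            return float(lp), obj, aux
        return float(out), None, None

    lp, obj, aux = evaluate(x)
    if not np.isfinite(lp):
        raise InitializationError("log-probability non-finite at the initial point")

    span = upper - lower
    cov = np.diag((initial_step_frac * span) ** 2)
    chol = np.linalg.cholesky(cov)
    sd = 2.38**2 / d
    eps = 1e-12 * np.diag(span**2)

    samples = np.empty((n_samples, d))
    logps = np.empty(n_samples)
    objectives = np.empty(n_samples) if obj is not None else None
    auxes = np.empty((n_samples, aux.size)) if aux is not None else None
    accepted = 0

    for i in range(n_samples):
        prop = x + chol @ rng.standard_normal(d)
        if np.all(prop >= lower) & np.all(prop <= upper):
            lp_p, obj_p, aux_p = evaluate(prop)
            if np.isfinite(lp_p) and np.log(rng.random()) < lp_p - lp:
                x, lp, obj, aux = prop, lp_p, obj_p, aux_p
                accepted += 1
        samples[i] = x
        logps[i] = lp
        if objectives is not None:
            objectives[i] = obj
        if auxes is not None:
            auxes[i] = aux

        if (i + 1) % adapt_interval == 0 and i + 1 >= max(2 * d, 20):
            hist_cov = np.cov(samples[: i + 1].T)
            adapted = sd * hist_cov + eps
            try:
                chol = np.linalg.cholesky(adapted)
            except np.linalg.LinAlgError:
                pass  # keep previous proposal covariance

    return ChainResult(
        samples=samples,
        logp=logps,
        accepted=accepted,
        burn_in=int(burn_frac * n_samples),
        seed=seed,
        param_names=tuple(param_names),
        objective=objectives,
        aux=auxes,
    )
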