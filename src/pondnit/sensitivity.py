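"""Sensitivity and identifiability analyses.

* :func:`local_sensitivity` — scaled local sensitivity functions by central
  finite differences, summarized by L1/L2 norms and an importance ranking;
* :func:`collinearity` — subset collinearity index gamma = 1/sqrt(smallest
  eigenvalue of the normalized sensitivity cross-product); gamma near 1
  means the subset is jointly identifiable, large gamma means the
  parameters can compensate each other (rule of thumb: subsets above ~15
  are practically unidentifiable);
* :func:`global_sensitivity` — uniform parameter sampling within bounds,
  correlating each parameter with the time-mean model outputs;
* :func:`mcmc_pair_stats` — posterior pairwise correlations and marginals;
* :func:`prediction_envelope` — min/median/max response bands over a chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .calibration import ChainResult
from .exceptions import IntegrationError, UndefinedMetricError
from .parameters import FREE_PARAMETERS, ParameterBounds
from .series import STATE_VARIABLES

__all__ = [
    "SensitivityMatrix",
    "local_sensitivity",
    "collinearity",
    "GlobalSensResult",
    "global_sensitivity",
    "PairStats",
    "mcmc_pair_stats",
    "prediction_envelope",
]


@dataclass
class SensitivityMatrix:
    """Scaled local sensitivities with per-parameter summaries.

    ``matrix`` rows are (variable, time) pairs, columns the free
    parameters; entries are dimensionless ``(dy/dtheta) * theta / sigma``.
    """

    matrix: pd.DataFrame
    L1: pd.Series
    L2: pd.Series
    ranking: pd.Series  # rank 1 = largest L1

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame({"L1": self.L1, "L2": self.L2, "rank": self.ranking})


def local_sensitivity(model, params=None, rel_step: float = 1e-4, scaling: str = "sd") -> SensitivityMatrix:
    """Central-finite-difference scaled sensitivities at the observation times.

    Each free parameter is perturbed by ``rel_step`` of its value; the
    response is scaled by the parameter value and by a per-variable scale
    (the observation standard deviation by default, the observation mean
    with ``scaling='mean'``).
    """
    if model.observations is None:
        raise ValueError("local sensitivity requires observations (for times and scaling)")
    params = params if params is not None else model.params
    obs = model.observations
    times = obs.times

    if scaling == "sd":
        sigma = obs.values.std(axis=0)
    elif scaling == "mean":
        sigma = obs.values.mean(axis=0)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    if np.any(sigma == 0):
        bad = [STATE_VARIABLES[i] for i in np.nonzero(sigma == 0)[0]]
        raise UndefinedMetricError(f"zero observation scale for {bad}")

    x0 = params.free_values()
    cols = {}
    for j, name in enumerate(FREE_PARAMETERS):
        h = rel_step * x0[j]
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        yp = model.predict(params.with_free_values(xp), times)
        ym = model.predict(params.with_free_values(xm), times)
        dy = (yp - ym) / (2.0 * h)           # (n_times, 3)
        cols[name] = (dy * x0[j] / sigma).T.ravel()  # variable-major rows

    index = pd.MultiIndex.from_product(
        [list(STATE_VARIABLES), times], names=["variable", "time_d"]
    )
    matrix = pd.DataFrame(cols, index=index)
    L1 = matrix.abs().mean(axis=0)
    L2 = np.sqrt((matrix**2).mean(axis=0))
    order = L1.sort_values(ascending=False).index
    ranking = pd.Series(np.arange(1, len(order) + 1), index=order).reindex(L1.index)
    return SensitivityMatrix(matrix=matrix, L1=L1, L2=L2, ranking=ranking)


def collinearity(
    sens: SensitivityMatrix | pd.DataFrame | np.ndarray,
    max_subset_size: int = 3,
    all_subsets: bool = False,
    parameter_names=None,
) -> pd.DataFrame:
    """Collinearity index for every parameter subset up to ``max_subset_size``.

    Columns are normalized to unit Euclidean norm; for a subset the index is
    ``1/sqrt(lambda_min)`` of the cross-product of the normalized columns.
    A parameter whose column is identically zero is unidentifiable alone and
    yields an infinite index for every subset containing it.
    """
    if isinstance(sens, SensitivityMatrix):
        S = sens.matrix.to_numpy()
        names = list(sens.matrix.columns)
    elif isinstance(sens, pd.DataFrame):
        S = sens.to_numpy()
        names = list(sens.columns)
    else:
        S = np.asarray(sens, dtype=float)
        names = list(parameter_names) if parameter_names is not None else [
            f"p{j}" for j in range(S.shape[1])
        ]
    n_rows, n_par = S.shape
    sizes = range(1, (n_par if all_subsets else min(max_subset_size, n_par)) + 1)
    if n_rows < max(sizes):
        raise ValueError("sensitivity matrix has fewer rows than the largest subset")

    norms = np.linalg.norm(S, axis=0)
    zero = norms == 0
    Sn = np.where(zero, 0.0, S / np.where(zero, 1.0, norms))

    records = []
    for size in sizes:
        for subset in combinations(range(n_par), size):
            if any(zero[list(subset)]):
                gamma = np.inf
            else:
                M = Sn[:, subset].T @ Sn[:, subset]
                lam = np.linalg.eigvalsh(M)[0]
                gamma = np.inf if lam <= 1e-30 else 1.0 / np.sqrt(lam)
            records.append(
                {
                    "subset": tuple(names[j] for j in subset),
                    "size": size,
                    "gamma": gamma,
                }
            )
    return pd.DataFrame.from_records(records)


@dataclass
class GlobalSensResult:
    """Uniform-sampling global sensitivity: samples, mean outputs, correlations."""

    samples: pd.DataFrame    # (n, n_par) parameter draws
    responses: pd.DataFrame  # (n, 3) time-mean ON/NH3/NO3
    corr: pd.DataFrame       # (n_par, 3) Pearson r
    n_failed: int = 0


def global_sensitivity(
    model,
    bounds: ParameterBounds,
    n: int = 1000,
    seed: int | None = 0,
    output_times=None,
) -> GlobalSensResult:
    """Correlate uniformly sampled parameters with time-mean model outputs.

    Draws ``n`` parameter vectors uniformly in the bounds box, simulates
    each over the forcing span and records the time-mean of each state.
    Failed simulations are dropped (at most 10% may fail).
    """
    if n < 30:
        raise ValueError("need n >= 30 samples")
    rng = np.random.default_rng(seed)
    draws = bounds.lower + rng.random((n, bounds.lower.size)) * bounds.span

    responses = np.full((n, 3), np.nan)
    n_failed = 0
    for i in range(n):
        try:
            states = model.predict(model.params.with_free_values(draws[i]), output_times)
        except (IntegrationError, ValueError):
            n_failed += 1
            continue
        responses[i] = states.mean(axis=0)
    if n_failed > 0.1 * n:
        raise IntegrationError(f"{n_failed}/{n} global-sensitivity simulations failed")

    ok = ~np.isnan(responses[:, 0])
    samples = pd.DataFrame(draws[ok], columns=list(FREE_PARAMETERS))
    resp = pd.DataFrame(responses[ok], columns=list(STATE_VARIABLES))
    corr = pd.DataFrame(
        {
            v: [np.corrcoef(samples[p], resp[v])[0, 1] for p in FREE_PARAMETERS]
            for v in STATE_VARIABLES
        },
        index=list(FREE_PARAMETERS),
    )
    return GlobalSensResult(samples=samples, responses=resp, corr=corr, n_failed=n_failed)


@dataclass
class PairStats:
    """Posterior pairwise correlations and marginal histogram counts."""

    corr: pd.DataFrame                 # (n_par, n_par); NaN where undefined
    hist_counts: pd.DataFrame          # (bins, n_par)
    bin_edges: pd.DataFrame            # (bins + 1, n_par)


def mcmc_pair_stats(chain: ChainResult, bounds: ParameterBounds | None = None, bins: int = 20) -> PairStats:
    """Pairwise Pearson correlations and 20-bin marginals of a chain.

    Histograms span the parameter bounds when given, else the sample range.
    Degenerate (constant) chain columns give NaN correlations.
    """
    post = chain.posterior
    if len(post) < 100:
        raise ValueError("need at least 100 post burn-in samples")
    names = list(chain.param_names) if chain.param_names else [
        f"p{j}" for j in range(post.shape[1])
    ]
    d = post.shape[1]

    corr = np.full((d, d), np.nan)
    sds = post.std(axis=0)
    for i in range(d):
        for j in range(d):
            if sds[i] > 0 and sds[j] > 0:
                corr[i, j] = np.corrcoef(post[:, i], post[:, j])[0, 1]
    counts = np.empty((bins, d))
    edges = np.empty((bins + 1, d))
    for j in range(d):
        lo = bounds.lower[j] if bounds is not None else post[:, j].min()
        hi = bounds.upper[j] if bounds is not None else post[:, j].max()
        if hi <= lo:
            hi = lo + 1.0
        c, e = np.histogram(post[:, j], bins=bins, range=(lo, hi))
        counts[:, j] = c
        edges[:, j] = e
    return PairStats(
        corr=pd.DataFrame(corr, index=names, columns=names),
        hist_counts=pd.DataFrame(counts, columns=names),
        bin_edges=pd.DataFrame(edges, columns=names),
    )


def prediction_envelope(
    model,
    chain: ChainResult,
    output_times=None,
    max_samples: int = 500,
    quantile_mode: str = "minmax",
) -> dict:
    """Per-time min/median/max response bands over post burn-in samples.

    The chain is thinned evenly to at most ``max_samples`` simulations.
    Returns ``{variable: DataFrame(time_d, min, median, max)}``.
    """
    if quantile_mode != "minmax":
        raise ValueError("only 'minmax' envelopes are supported")
    post = chain.posterior
    if len(post) < 1:
        raise ValueError("need at least one post burn-in sample")
    idx = np.unique(np.linspace(0, len(post) - 1, min(max_samples, len(post))).astype(int))

    if output_times is None:
        t_lo, t_hi = model.forcing.span
        output_times = np.arange(np.ceil(t_lo), np.floor(t_hi) + 0.5)
    output_times = np.asarray(output_times, dtype=float)

    trajectories = []
    for i in idx:
        try:
            trajectories.append(model.predict(model.params.with_free_values(post[i]), output_times))
        except (IntegrationError, ValueError):
            continue
    if not trajectories:
        raise IntegrationError("all envelope simulations failed")
    stack = np.stack(trajectories)  # (m, n_times, 3)

    out = {}
    for k, v in enumerate(STATE_VARIABLES):
        out[v] = pd.DataFrame(
            {
                "time_d": output_times,
                "min": stack[:, :, k].min(axis=0),
                "median": np.median(stack[:, :, k], axis=0),
                "max": stack[:, :, k].max(axis=0),
            }
        )
    return out
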