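"""GLUE (generalized likelihood uncertainty estimation) analysis.

Sampled parameter sets are classified per output variable as behavioral
(NSE likelihood >= 0, i.e. at least as good as predicting the observed
mean) or non-behavioral (NSE < 0).  The separation between the empirical
CDFs of behavioral and non-behavioral parameter values — quantified here
by the Kolmogorov-Smirnov distance — measures how sensitive that variable's
likelihood is to the parameter: far-apart CDFs mean high sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import FREE_PARAMETERS
from .series import STATE_VARIABLES

__all__ = ["GlueEnsemble", "evaluate_ensemble", "dotty_data", "CdfSeparation", "cdf_separation"]


@dataclass
class GlueEnsemble:
    """Parameter ensemble with per-variable NSE likelihoods and behavioral flags."""

    samples: pd.DataFrame   # (n, n_par)
    nse: pd.DataFrame       # (n, 3), -inf for failed simulations
    threshold: float = 0.0

    @property
    def flags(self) -> pd.DataFrame:
        """Behavioral flag per (sample, variable): NSE >= threshold."""
        return self.nse >= self.threshold

    @property
    def joint_flag(self) -> pd.Series:
        """Behavioral in all three variables simultaneously."""
        return self.flags.all(axis=1)

    def behavioral_counts(self) -> pd.Series:
        return self.flags.sum(axis=0)

    def __len__(self) -> int:
        return len(self.samples)

    def to_dataframe(self) -> pd.DataFrame:
        df = self.samples.copy()
        for v in self.nse.columns:
            df[f"nse_{v.lower()}"] = self.nse[v].to_numpy()
        for v in self.nse.columns:
            df[f"behavioral_{v.lower()}"] = self.flags[v].to_numpy()
        return df


def evaluate_ensemble(samples, model=None, chain=None, threshold: float = 0.0) -> GlueEnsemble:
    """Per-sample, per-variable NSE likelihoods for an ensemble.

    When ``chain`` carries per-variable NSEs recorded during MCMC they are
    reused directly; otherwise each sample is simulated against the
    model's calibration-window observations.  Failed simulations are
    marked non-behavioral with NSE = -inf.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 100:
        raise ValueError("GLUE needs at least 100 samples")
    names = list(FREE_PARAMETERS) if samples.shape[1] == len(FREE_PARAMETERS) else [
        f"p{j}" for j in range(samples.shape[1])
    ]

    if chain is not None and chain.aux is not None and len(chain.aux) == len(samples):
        nse_values = np.asarray(chain.aux, dtype=float)
    else:
        if model is None:
            raise ValueError("need a model to simulate the ensemble")
        cached = model._calibration_arrays()
        nse_values = np.empty((len(samples), 3))
        for i, x in enumerate(samples):
            v = model._eval_free(x, cached)
            nse_values[i] = v if v is not None else -np.inf

    return GlueEnsemble(
        samples=pd.DataFrame(samples, columns=names),
        nse=pd.DataFrame(nse_values, columns=list(STATE_VARIABLES)),
        threshold=threshold,
    )


def dotty_data(ensemble: GlueEnsemble) -> pd.DataFrame:
    """Long-format (parameter value, NSE) scatter table for dotty plots.

    One row per (sample, parameter, variable); the behavioral threshold is
    stored in ``df.attrs['threshold']`` for the horizontal criterion line.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    frames = []
    for p in ensemble.samples.columns:
        for v in ensemble.nse.columns:
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": p,
                        "value": ensemble.samples[p].to_numpy(),
                        "variable": v,
                        "nse": ensemble.nse[v].to_numpy(),
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    df.attrs["threshold"] = ensemble.threshold
    return df


@dataclass
class CdfSeparation:
    """Behavioral vs non-behavioral CDF separation per (parameter, variable)."""

    table: pd.DataFrame  # parameter, variable, ks, n_behavioral, n_non_behavioral, defined
    cdfs: dict           # (parameter, variable) -> DataFrame(value, cdf_behavioral, cdf_non_behavioral)

    def ks(self, parameter: str, variable: str) -> float:
        row = self.table[
            (self.table["parameter"] == parameter) & (self.table["variable"] == variable)
        ]
        if row.empty:
            raise KeyError((parameter, variable))
        return float(row["ks"].iloc[0])


def cdf_separation(ensemble: GlueEnsemble, grid_points: int = 101) -> CdfSeparation:
    """Empirical CDFs and KS distance of behavioral vs non-behavioral values.

    For each (parameter, variable): the parameter values of behavioral and
    non-behavioral samples form two empirical distributions; their
    Kolmogorov-Smirnov distance is the separation statistic.  A variable
    with an empty class is flagged undefined (KS = NaN) rather than raising.
    """
    records = []
    cdfs = {}
    for v in ensemble.nse.columns:
        flag = ensemble.flags[v].to_numpy()
        for p in ensemble.samples.columns:
            x = ensemble.samples[p].to_numpy()
            beh, non = x[flag], x[~flag]
            defined = beh.size > 0 and non.size > 0
            if defined:
                ks = float(stats.ks_2samp(beh, non, method="asymp").statistic)
                grid = np.linspace(x.min(), x.max(), grid_points)
                cdfs[(p, v)] = pd.DataFrame(
                    {
                        "value": grid,
                        "cdf_behavioral": np.searchsorted(np.sort(beh), grid, side="right")
                        / beh.size,
                        "cdf_non_behavioral": np.searchsorted(np.sort(non), grid, side="right")
                        / non.size,
                    }
                )
            else:
                ks = np.nan
            records.append(
                {
                    "parameter": p,
                    "variable": v,
                    "ks": ks,
                    "n_behavioral": int(beh.size),
                    "n_non_behavioral": int(non.size),
                    "defined": defined,
                }
            )
    return CdfSeparation(table=pd.DataFrame.from_records(records), cdfs=cdfs)
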