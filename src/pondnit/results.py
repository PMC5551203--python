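"""Fit results container with diagnostics, summary table and downstream analyses."""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .calibration import ChainResult, PseudoSearchResult
from .parameters import FREE_PARAMETERS, ModelParameters, ParameterBounds

__all__ = ["PondFitResults"]


@dataclass
class PondFitResults:
    """Results of :meth:`pondnit.model.PondModel.fit`.

    Carries the best-fit parameters, the full MCMC chain, per-variable
    NSE / Pearson-r tables for the calibration and validation windows, and
    hooks into the sensitivity, envelope and GLUE analyses that consume
    the chain.
    """

    model: object
    params: ModelParameters
    objective_value: float
    nse: pd.DataFrame
    r: pd.DataFrame
    pseudo: PseudoSearchResult
    chain: ChainResult
    bounds: ParameterBounds
    seed: int | None
    n_obs_calibration: int

    # ------------------------------------------------------------ summaries
    def posterior_std(self) -> pd.Series:
        """Post burn-in posterior standard deviation per free parameter."""
        return pd.Series(self.chain.posterior.std(axis=0), index=list(FREE_PARAMETERS))

    def params_table(self) -> pd.DataFrame:
        post = self.chain.posterior
        return pd.DataFrame(
            {
                "estimate": self.params.free_values(),
                "post_mean": post.mean(axis=0),
                "post_std": post.std(axis=0),
                "lower": self.bounds.lower,
                "upper": self.bounds.upper,
            },
            index=list(FREE_PARAMETERS),
        )

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        lines = []
        lines.append("Pond nitrogen model fit")
        lines.append("=" * 64)
        lines.append(
            f"calibration points: {self.n_obs_calibration}   "
            f"objective (mean NSE): {self.objective_value:.4f}"
        )
        lines.append(
            f"random-search evals: {self.pseudo.n_eval}   "
            f"MCMC samples: {len(self.chain)}   "
            f"acceptance: {self.chain.acceptance_rate:.3f}"
        )
        lines.append("")
        lines.append("Parameters (posterior from post burn-in chain)")
        lines.append(self.params_table().to_string(float_format=lambda v: f"{v:.5g}"))
        lines.append("")
        lines.append("Goodness of fit (NSE)")
        lines.append(self.nse.to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        lines.append("Correlation (r)")
        lines.append(self.r.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    # --------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "objective": float(self.objective_value),
            "nse": {c: self.nse[c].to_dict() for c in self.nse.columns},
            "r": {c: self.r[c].to_dict() for c in self.r.columns},
            "acceptance_rate": self.chain.acceptance_rate,
            "n_mcmc": len(self.chain),
            "burn_in": self.chain.burn_in,
            "seed": self.seed,
            "bounds": self.bounds.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def chain_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.chain.samples, columns=list(FREE_PARAMETERS))
        df["logp"] = self.chain.logp
        if self.chain.objective is not None:
            df["objective"] = self.chain.objective
        if self.chain.aux is not None:
            for j, v in enumerate(("nse_on", "nse_nh3", "nse_no3")):
                df[v] = self.chain.aux[:, j]
        return df

    # ------------------------------------------------------- chain analyses
    def pair_stats(self, bins: int = 20):
        """Pairwise posterior correlations and marginal histograms."""
        from .sensitivity import mcmc_pair_stats

        return mcmc_pair_stats(self.chain, self.bounds, bins=bins)

    def prediction_envelope(self, output_times=None, max_samples: int = 500):
        """Min/median/max response bands over the posterior chain."""
        from .sensitivity import prediction_envelope

        return prediction_envelope(
            self.model, self.chain, output_times=output_times, max_samples=max_samples
        )

    def glue(self):
        """GLUE behavioral classification of the chain samples."""
        from .glue import evaluate_ensemble

        return evaluate_ensemble(self.chain.samples, self.model, chain=self.chain)
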