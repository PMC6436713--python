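"""Model / Results interface to the hierarchical spatial ordinal model.

Usage follows the fit-object convention of mainstream statistical
packages::

    model = SpatialOrdinalModel.from_dataframe(
        df, blocks=schema, adjacency=adj, structure="convolution")
    results = model.fit(McmcConfig(n_draws=2000, burnin=1000, seed=1))
    print(results.summary())
    results.dic
    results.county_effects()

The model object holds the data, adjacency and specification; ``fit``
runs the Metropolis-within-Gibbs sampler and returns a results object
carrying the posterior draws, odds-ratio tables, DIC, diagnostics and the
county-effect surfaces used for mapping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adjacency import AdjacencyStructure
from .datasets import OrdinalDataset
from .likelihood import deviance, log_likelihood, structure_uses_phi, structure_uses_u
from .priors import PriorSpec
from .sampler import McmcConfig, ModelSpec, PosteriorDraws, run_mcmc
from .summaries import (
    DicResult,
    FitSummary,
    compute_dic,
    diagnostics,
    posterior_mean_state,
    summarize,
)

__all__ = ["SpatialOrdinalModel", "SpatialOrdinalResults"]


class SpatialOrdinalModel:
    """Hierarchical proportional-odds model for patients nested in
    facilities nested in counties, with iid, CAR or convolution county
    effects."""

    def __init__(
        self,
        dataset: OrdinalDataset,
        adjacency: AdjacencyStructure = None,
        structure: str = "convolution",
        covariates=None,
        prior: PriorSpec = None,
        facility_effects: bool = True,
    ):
        self.dataset = dataset
        self.adjacency = adjacency
        self.spec = ModelSpec(
            structure=structure,
            covariates=list(covariates) if covariates is not None else None,
            prior=prior or PriorSpec(),
            facility_effects=facility_effects,
        )
        if structure_uses_phi(structure) and adjacency is None:
            raise ValueError(f"structure {structure!r} requires an adjacency structure")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        blocks: dict,
        adjacency: AdjacencyStructure = None,
        outcome: str = "outcome",
        facility: str = "facility_id",
        county: str = "county_id",
        **kwargs,
    ) -> "SpatialOrdinalModel":
        dataset = OrdinalDataset.from_frame(
            df, blocks=blocks, outcome=outcome, facility=facility, county=county
        )
        return cls(dataset, adjacency=adjacency, **kwargs)

    def loglike(self, state, use_weights: bool = False) -> float:
        return log_likelihood(self.dataset, state, self.spec.structure, use_weights)

    def deviance(self, state) -> float:
        return deviance(self.dataset, state, self.spec.structure)

    def fit(self, config: McmcConfig = None) -> "SpatialOrdinalResults":
        config = config or McmcConfig()
        draws = run_mcmc(self.dataset, self.adjacency, self.spec, config)
        return SpatialOrdinalResults(self, draws)


class SpatialOrdinalResults:
    """Posterior fit: draws, summaries, DIC, diagnostics, county surfaces."""

    def __init__(self, model: SpatialOrdinalModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self._dic = None

    # -- summaries ------------------------------------------------------
    def summary(self, levels=(0.85, 0.95)) -> FitSummary:
        return summarize(self.draws, levels=levels)

    @property
    def params(self) -> pd.Series:
        """Posterior mean coefficients (log-odds scale)."""
        means = self.draws.stacked("beta").mean(axis=0)
        return pd.Series(means, index=self.draws.param_names["beta"])

    @property
    def odds_ratios(self) -> pd.Series:
        ors = np.exp(self.draws.stacked("beta")).mean(axis=0)
        return pd.Series(ors, index=self.draws.param_names["beta"])

    def credible_interval(self, level: float = 0.95, scale: str = "or") -> pd.DataFrame:
        arr = self.draws.stacked("beta")
        if scale == "or":
            arr = np.exp(arr)
        lo, hi = np.quantile(arr, [(1 - level) / 2, 1 - (1 - level) / 2], axis=0)
        return pd.DataFrame(
            {"lower": lo, "upper": hi}, index=self.draws.param_names["beta"]
        )

    @property
    def posterior_mean_state(self):
        return posterior_mean_state(self.draws)

    # -- fit quality ----------------------------------------------------
    @property
    def dic(self) -> DicResult:
        if self._dic is None:
            self._dic = compute_dic(self.draws, self.model.dataset, self.model.spec)
        return self._dic

    def diagnostics(self, **kwargs) -> dict:
        return diagnostics(self.draws, **kwargs)

    # -- spatial surfaces ------------------------------------------------
    def county_effects(self, levels=(0.95,)) -> pd.DataFrame:
        """Posterior mean/median/interval of the county odds multiplier
        exp(u + phi) under the fitted structure."""
        structure = self.draws.structure
        if not structure_uses_phi(structure):
            raise ValueError(
                "county-effect surfaces need a structured or convolution fit"
            )
        total = self.draws.stacked("phi")
        if structure_uses_u(structure):
            total = total + self.draws.stacked("u")
        mult = np.exp(total)
        adjacency = self.model.adjacency
        ids = adjacency.county_ids if adjacency is not None else list(range(mult.shape[1]))
        out = pd.DataFrame({
            "county_id": ids,
            "mean": mult.mean(axis=0),
            "median": np.median(mult, axis=0),
        })
        for lv in levels:
            lo, hi = np.quantile(mult, [(1 - lv) / 2, 1 - (1 - lv) / 2], axis=0)
            out[f"lower_{lv:g}"] = lo
            out[f"upper_{lv:g}"] = hi
        return out

    # -- persistence ----------------------------------------------------
    def save(self, directory) -> None:
        self.draws.save(directory)

    # -- plotting -------------------------------------------------------
    def plot_trace(self, group: str = "beta", ax=None):
        import matplotlib.pyplot as plt

        arr = self.draws.samples[group]
        if ax is None:
            _, ax = plt.subplots()
        for c in range(arr.shape[0]):
            for j in range(arr.shape[2]):
                ax.plot(arr[c, :, j], lw=0.5)
        ax.set_xlabel("retained draw")
        ax.set_ylabel(group)
        return ax
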