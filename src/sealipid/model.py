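"""Model / Results facade over the sampler, selection and reporting layers.

Typical use::

    from sealipid import LipidStateModel, simulate_population, SimulationConfig

    pop = simulate_population(SimulationConfig(n_individuals=6, seed=1))
    model = LipidStateModel.from_simulation(pop)
    res = model.fit(n_iterations=4000, seed=1)
    print(res.summary_text())
    res.trajectories()          # daily posterior lipid mass per seal
    res.log_marginal_likelihood()
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ModelSpec, PriorConfig, SamplerConfig
from .preprocessing import SealDataset, prepare
from .reporting import condition_trajectories, missingness_report, summarize
from .sampler import PosteriorChains, concat_chains, diagnostics, run_mcmc
from .selection import ChibResult, chib_log_marginal

__all__ = ["LipidStateModel", "LipidStateResults"]


class LipidStateModel:
    """Hierarchical Bayesian state-space model of daily lipid stores.

    Wraps a model-ready :class:`SealDataset` together with its prior
    configuration; :meth:`fit` runs the Metropolis-within-Gibbs sampler
    and returns a :class:`LipidStateResults`.
    """

    def __init__(self, dataset: SealDataset, priors: Optional[PriorConfig] = None):
        self.dataset = dataset
        self.priors = priors or PriorConfig()

    @classmethod
    def from_tables(cls, dives, track, captures, states=None,
                    spec: Optional[ModelSpec] = None,
                    priors: Optional[PriorConfig] = None,
                    **prepare_kwargs) -> "LipidStateModel":
        """Build from raw CSV-shaped tables (see preprocessing.prepare)."""
        _, dataset = prepare(dives, track, captures, states, spec, **prepare_kwargs)
        return cls(dataset, priors)

    @classmethod
    def from_simulation(cls, population, spec: Optional[ModelSpec] = None,
                        priors: Optional[PriorConfig] = None) -> "LipidStateModel":
        """Build directly from a synthetic population bundle."""
        return cls(population.dataset(spec), priors)

    def fit(self, n_iterations: int = 4000, n_burnin: Optional[int] = None,
            thin: int = 1, seed: int = 0, n_chains: int = 1,
            **sampler_kwargs) -> "LipidStateResults":
        """Run the sampler; chains use seeds derived from ``seed``."""
        chain_list = []
        for c in range(n_chains):
            cfg = SamplerConfig(n_iterations=n_iterations, n_burnin=n_burnin,
                                thin=thin, seed=(seed + 7919 * c) % (2 ** 31),
                                n_chains=n_chains, **sampler_kwargs)
            chain_list.append(run_mcmc(self.dataset, self.priors, cfg))
        return LipidStateResults(self, chain_list)


class LipidStateResults:
    """Posterior draws plus summaries, diagnostics and model selection."""

    def __init__(self, model: LipidStateModel, chain_list: Sequence[PosteriorChains]):
        self.model = model
        self.chain_list = list(chain_list)
        self.chains = (chain_list[0] if len(chain_list) == 1
                       else concat_chains(self.chain_list))

    # -- summaries ---------------------------------------------------------
    def summary(self, original_scale: bool = True) -> pd.DataFrame:
        return summarize(self.chains, original_scale=original_scale)

    def summary_text(self) -> str:
        df = self.summary()
        header = (f"Lipid state-space model: {self.model.dataset.n_individuals} "
                  f"individuals, {self.model.dataset.n_transitions} transitions, "
                  f"{self.chains.n_draws} stored draws\n")
        return header + df.to_string(index=False,
                                     float_format=lambda v: f"{v: .3f}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.summary_text()

    def trajectories(self) -> pd.DataFrame:
        return condition_trajectories(self.chains)

    def missingness_report(self, drift_mask=None, covariate_truth=None,
                           **kwargs) -> pd.DataFrame:
        return missingness_report(self.chains, drift_mask, covariate_truth,
                                  **kwargs)

    # -- diagnostics ---------------------------------------------------------
    def diagnostics(self) -> pd.DataFrame:
        return diagnostics(self.chain_list)

    @property
    def acceptance(self) -> dict:
        return self.chains.acceptance

    # -- model selection -----------------------------------------------------
    def log_marginal_likelihood(self, **kwargs) -> ChibResult:
        return chib_log_marginal(self.chains, self.model.dataset,
                                 self.model.priors, **kwargs)

    # -- posterior intervals on the original covariate scale -----------------
    def credible_interval(self, parameter: str, level: float = 0.95,
                          original_scale: bool = False) -> tuple:
        """Equal-tailed credible interval for one named parameter."""
        draws = self._draws_for(parameter, original_scale)
        lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2])
        return float(lo), float(hi)

    def _draws_for(self, parameter: str, original_scale: bool = False):
        ch = self.chains
        if parameter == "alpha1":
            return ch.alpha[:, 0]
        if parameter == "alpha2":
            return ch.alpha[:, 1]
        if parameter in ("tau2", "sigma2"):
            return getattr(ch, parameter)
        if parameter in ch.columns:
            b = ch.beta_original_scale() if original_scale else ch.beta
            return b[:, ch.columns.index(parameter)]
        raise KeyError(parameter)
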