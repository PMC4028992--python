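"""Configuration blocks: model specification, priors and sampler settings.

Each block is a plain dataclass with ``to_dict``/``from_dict`` so a whole
candidate model can be serialised to JSON (or YAML via any external tool)
and passed around model-selection code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

__all__ = ["ModelSpec", "PriorConfig", "SamplerConfig", "ModelCandidate"]

#: covariates of the final northern-elephant-seal process model: intercept,
#: daily surface transit, number of drift dives, the (latent-dependent)
#: lipid:lean tissue ratio, departure lipid percentage and the short-term
#: behavioural state index.  Foraging-location x phase indicators are added
#: by the design builder when ``include_location_phase`` is set.
DEFAULT_COVARIATES = (
    "intercept",
    "transit",
    "n_drift_dives",
    "lipid_lean_ratio",
    "departure_lipid_pct",
    "state_index",
)


@dataclass
class ModelSpec:
    """Defines one candidate model: covariates, random effects and bounds.

    Parameters
    ----------
    covariates
        Ordered design columns (location x phase indicators are appended
        separately when ``include_location_phase`` is true).
    random_effects
        Subset of ``covariates`` given per-individual Gaussian random
        effects (q < p).
    beta_bounds
        Truncation bounds (b_min, b_max) per coefficient.  The number of
        drift dives defaults to b_min = 0: more drift dives are assumed to
        accompany lipid gain, never loss.
    reference_cell
        (location, phase) cell dropped from the location x phase coding;
        for the northern species this is coastal animals in the foraging
        phase, for the southern species pelagic animals in the foraging
        phase.
    non_lipid_form
        Functional form (1-6) of the fixed non-lipid tissue series.
    transit_kind
        Which transit covariate enters the process model: "daily" or the
        5-day running value "running5".
    standardize
        Z-score continuous covariates (within dataset) before fitting;
        reports can be back-transformed to the original scale.
    """

    covariates: tuple = DEFAULT_COVARIATES
    random_effects: tuple = ("intercept",)
    beta_bounds: dict = field(default_factory=lambda: {"n_drift_dives": (0.0, math.inf)})
    reference_cell: tuple = ("coastal", "foraging")
    include_location_phase: bool = True
    non_lipid_form: int = 6
    transit_kind: str = "daily"
    standardize: bool = True
    latent_column: str = "lipid_lean_ratio"
    foraging_threshold_km: float = 30.0

    def __post_init__(self):
        self.covariates = tuple(self.covariates)
        self.random_effects = tuple(self.random_effects)
        if not 1 <= self.non_lipid_form <= 6:
            raise ValueError("non_lipid_form must be in 1..6")
        if self.transit_kind not in ("daily", "running5"):
            raise ValueError("transit_kind must be 'daily' or 'running5'")
        unknown = set(self.random_effects) - set(self.covariates)
        if unknown:
            raise ValueError(f"random effects not among covariates: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta_bounds"] = {k: list(v) for k, v in self.beta_bounds.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["beta_bounds"] = {k: tuple(v) for k, v in d.get("beta_bounds", {}).items()}
        d["reference_cell"] = tuple(d["reference_cell"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass
class PriorConfig:
    """Hyperparameters of the parameter models.

    The observation slope/intercept pair has a bivariate normal prior
    truncated to a positive slope (drift rate rises with lipid content).
    Observation and process variances have informative inverse-gamma
    priors whose prior means match the stated error ceilings -- about
    0.1 m/s of unexplained drift-rate error and 2 kg/day of unexplained
    lipid error -- weighted proportional to sample size through
    ``variance_prior_weight`` (effective prior sample size = weight x N).
    Fixed effects have independent normal priors truncated to
    ``beta_bounds``; ``beta_prior_var=inf`` recovers a flat prior (note a
    flat prior leaves the marginal likelihood undefined, so model
    selection requires the proper default).  The random-effects covariance
    has an inverse-Wishart prior IW(diag(1,q), q+1).
    """

    alpha_mean: tuple = (0.0, 1.0)
    alpha_var: tuple = (100.0, 100.0)  # diagonal prior covariance
    tau2_prior_mean: float = 0.01     # (0.1 m/s)^2
    sigma2_prior_mean: float = 4.0    # (2 kg/day)^2
    variance_prior_weight: float = 0.1
    beta_prior_mean: float = 0.0
    beta_prior_var: float = 100.0
    iw_scale: Optional[list] = None   # default diag(1, q)
    iw_df: Optional[int] = None       # default q + 1

    def inverse_gamma_hyper(self, prior_mean: float, n: int) -> tuple:
        """(shape, scale) of an IG prior with the given mean and an
        effective prior sample size of ``variance_prior_weight * n``."""
        n0 = max(self.variance_prior_weight * n, 1.0)
        shape = 2.0 + n0 / 2.0
        scale = (shape - 1.0) * prior_mean
        return shape, scale

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorConfig":
        d = dict(d)
        for k in ("alpha_mean", "alpha_var"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SamplerConfig:
    """Metropolis-within-Gibbs settings.

    ``latent_proposal_sd`` (kg) is the random-walk step for single-day
    latent updates; with ``adapt`` it is tuned by Robbins-Monro during
    burn-in toward 30-45% acceptance.  ``fast_path_threshold`` is the
    minimum process mean / sigma ratio beyond which the truncated-normal
    normaliser is treated as 1 and the conjugate draws are exact.
    """

    n_iterations: int = 4000
    n_burnin: Optional[int] = None
    thin: int = 1
    seed: Optional[int] = None
    latent_proposal_sd: float = 0.5
    adapt: bool = True
    n_chains: int = 1
    fast_path_threshold: float = 4.0
    store_latent: bool = True

    def resolved_burnin(self) -> int:
        b = self.n_burnin if self.n_burnin is not None else self.n_iterations // 4
        if b >= self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        return b

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ModelCandidate:
    """One entry in a model-selection run."""

    label: str
    model_spec: ModelSpec
    prior_config: Optional[PriorConfig] = None

    @property
    def non_lipid_form(self) -> int:
        return self.model_spec.non_lipid_form
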