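"""Shared fixtures: small hand-built datasets for sampler-level tests."""

import numpy as np
import pytest

from sealipid import ModelSpec, SealArrays, SealDataset


def make_toy_dataset(n_seals=2, T=8, seed=0, covariates=("intercept", "x1"),
                     random_effects=("intercept",), beta_bounds=None,
                     latent_column="none", R0=300.0):
    """A tiny dataset with a latent-independent design (unless the
    lipid:lean column is requested), convenient for conjugate algebra."""
    rng = np.random.default_rng(seed)
    covs = list(covariates)
    spec = ModelSpec(covariates=tuple(covs), random_effects=tuple(random_effects),
                     beta_bounds=beta_bounds or {}, include_location_phase=False,
                     standardize=False, latent_column=latent_column)
    seals = []
    for i in range(n_seals):
        R = R0 + 0.5 * np.arange(T + 1)
        X = np.column_stack([np.ones(T) if c == "intercept"
                             else np.zeros(T) if c == latent_column
                             else rng.standard_normal(T)
                             for c in covs])
        h = rng.integers(0, 6, T + 1)
        L_true = 60.0 + np.cumsum(rng.normal(0.0, 1.0, T + 1))
        D = np.where(h > 0, -0.5 + 1.2 * L_true / R + rng.normal(0, 0.1, T + 1),
                     np.nan)
        seals.append(SealArrays(f"s{i}", D, h, R, X, float(L_true[0]),
                                float(L_true[-1])))
    return SealDataset(seals=seals, columns=covs, spec=spec)


@pytest.fixture
def toy_dataset():
    return make_toy_dataset()
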