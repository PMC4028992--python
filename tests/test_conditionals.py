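"""Gibbs conditionals against independently coded conjugate algebra."""

import math

import numpy as np
import pytest

from sealipid import PriorConfig
from sealipid._latent import latent_sweep, latent_sweep_py
from sealipid.sampler import (G_conditional, _draw_bounded_mvn, alpha_conditional,
                              beta_conditional, gamma_conditional,
                              sigma2_conditional, tau2_conditional)

from conftest import make_toy_dataset


def _latent_lists(dataset, rng):
    return [np.linspace(s.L0, s.LT, s.T + 1) + rng.normal(0, 0.5, s.T + 1)
            * np.r_[0, np.ones(s.T - 1), 0] for s in dataset.seals]


# ---------------------------------------------------------------------------
# alpha
# ---------------------------------------------------------------------------

def test_alpha_conditional_matches_weighted_regression_oracle():
    ds = make_toy_dataset(seed=3)
    rng = np.random.default_rng(0)
    L = _latent_lists(ds, rng)
    prior = PriorConfig()
    tau2 = 0.02
    m, V = alpha_conditional(ds, L, tau2, prior)

    # independent algebra: weighted least squares blended with the prior
    rows, ys, ws = [], [], []
    for i, seal in enumerate(ds.seals):
        msk = seal.obs_mask
        rows.append(np.column_stack([np.ones(msk.sum()),
                                     L[i][msk] / seal.R[msk]]))
        ys.append(seal.D[msk])
        ws.append(seal.h[msk] / tau2)
    Z = np.vstack(rows)
    y = np.concatenate(ys)
    w = np.concatenate(ws)
    A0inv = np.diag(1.0 / np.array(prior.alpha_var))
    Vinv = A0inv + (Z * w[:, None]).T @ Z
    V_o = np.linalg.inv(Vinv)
    m_o = V_o @ (A0inv @ np.array(prior.alpha_mean) + Z.T @ (w * y))
    assert np.allclose(m, m_o, atol=1e-8)
    assert np.allclose(V, V_o, atol=1e-8)


def test_alpha_conditional_concentrates_on_exact_linear_data():
    """With tau2 -> 0 and D exactly linear in L/R, the conditional mean
    pins the generating intercept and slope."""
    ds = make_toy_dataset(seed=4)
    for seal in ds.seals:
        seal.D[:] = 0.3 + 0.9 * np.linspace(seal.L0, seal.LT, seal.T + 1) / seal.R
        seal.h[:] = 5
    L = [np.linspace(s.L0, s.LT, s.T + 1) for s in ds.seals]
    m, V = alpha_conditional(ds, L, 1e-10, PriorConfig())
    assert np.allclose(m, [0.3, 0.9], atol=1e-4)
    assert np.all(np.sqrt(np.diag(V)) < 1e-3)


def test_alpha_conditional_errors_without_observations():
    ds = make_toy_dataset(seed=5)
    for seal in ds.seals:
        seal.h[:] = 0
        seal.D[:] = np.nan
    with pytest.raises(ValueError):
        alpha_conditional(ds, [np.linspace(s.L0, s.LT, s.T + 1) for s in ds.seals],
                          0.01, PriorConfig())


# ---------------------------------------------------------------------------
# beta
# ---------------------------------------------------------------------------

def test_beta_conditional_intercept_closed_form():
    """With the second covariate centred (orthogonal to the intercept),
    the intercept's conditional under a flat prior is exactly the mean
    daily increment with variance sigma2 / N."""
    ds = make_toy_dataset(covariates=("intercept", "x1"), seed=6)
    x1 = np.concatenate([s.X[:, 1] for s in ds.seals])
    shift = x1.mean()
    for s in ds.seals:
        s.X[:, 1] -= shift
    rng = np.random.default_rng(1)
    L = _latent_lists(ds, rng)
    sigma2 = 2.5
    prior = PriorConfig(beta_prior_var=math.inf)   # flat
    gamma = np.zeros((2, 1))
    m, V = beta_conditional(ds, [s.X for s in ds.seals], L, gamma, sigma2, prior)
    incs = np.concatenate([np.diff(Li) for Li in L])
    assert m[0] == pytest.approx(incs.mean(), abs=1e-8)
    assert V[0, 0] == pytest.approx(sigma2 / len(incs), abs=1e-8)


def test_beta_conditional_general_oracle_and_singular_design():
    ds = make_toy_dataset(covariates=("intercept", "x1", "x2"), seed=7)
    rng = np.random.default_rng(2)
    L = _latent_lists(ds, rng)
    gamma = rng.normal(0, 0.1, (2, 1))
    sigma2 = 1.7
    prior = PriorConfig(beta_prior_var=50.0)
    m, V = beta_conditional(ds, [s.X for s in ds.seals], L, gamma, sigma2, prior)

    X = np.vstack([s.X for s in ds.seals])
    y = np.concatenate([np.diff(L[i]) - ds.seals[i].X[:, [0]] @ gamma[i]
                        for i in range(2)])
    Vinv_o = X.T @ X / sigma2 + np.eye(3) / 50.0
    m_o = np.linalg.solve(Vinv_o, X.T @ y / sigma2)
    assert np.allclose(m, m_o, atol=1e-8)
    assert np.allclose(V, np.linalg.inv(Vinv_o), atol=1e-8)

    # duplicated covariate column under a flat prior: singular design
    ds_dup = make_toy_dataset(covariates=("intercept", "x1"), seed=7)
    for seal in ds_dup.seals:
        seal.X[:, 1] = 1.0   # duplicate of the intercept
    with pytest.raises(np.linalg.LinAlgError):
        beta_conditional(ds_dup, [s.X for s in ds_dup.seals], L,
                         gamma, 1.0, PriorConfig(beta_prior_var=math.inf))


# ---------------------------------------------------------------------------
# variances
# ---------------------------------------------------------------------------

def test_tau2_conditional_conjugate_shape_and_scale():
    ds = make_toy_dataset(seed=8)
    L = [np.linspace(s.L0, s.LT, s.T + 1) for s in ds.seals]
    prior = PriorConfig()
    alpha = np.array([-0.4, 1.1])
    sh, sc = tau2_conditional(ds, L, alpha, prior)
    a0, b0 = prior.inverse_gamma_hyper(prior.tau2_prior_mean, ds.n_obs)
    n = ds.n_obs
    assert sh == pytest.approx(a0 + n / 2.0, abs=1e-12)
    ss = 0.0
    for i, seal in enumerate(ds.seals):
        msk = seal.obs_mask
        mu = alpha[0] + alpha[1] * L[i][msk] / seal.R[msk]
        ss += np.sum(seal.h[msk] * (seal.D[msk] - mu) ** 2)
    assert sc == pytest.approx(b0 + ss / 2.0, abs=1e-8)


def test_sigma2_conditional_oracle():
    ds = make_toy_dataset(seed=9)
    rng = np.random.default_rng(3)
    L = _latent_lists(ds, rng)
    prior = PriorConfig()
    mus = [L[i][:-1] + ds.seals[i].X @ np.array([0.2, -0.1]) for i in range(2)]
    sh, sc = sigma2_conditional(ds, mus, L, prior)
    a0, b0 = prior.inverse_gamma_hyper(prior.sigma2_prior_mean, ds.n_transitions)
    ss = sum(float(np.sum((L[i][1:] - mus[i]) ** 2)) for i in range(2))
    assert sh == pytest.approx(a0 + ds.n_transitions / 2.0, abs=1e-12)
    assert sc == pytest.approx(b0 + ss / 2.0, abs=1e-8)


# ---------------------------------------------------------------------------
# random effects
# ---------------------------------------------------------------------------

def test_gamma_conditional_oracle_and_weak_prior_limit():
    ds = make_toy_dataset(seed=10)
    rng = np.random.default_rng(4)
    L = _latent_lists(ds, rng)
    beta = np.array([0.3, 0.1])
    sigma2 = 1.2
    seal = ds.seals[0]
    G = np.array([[0.25]])
    m, V = gamma_conditional(seal, seal.X, L[0], beta, G, sigma2, ds.re_idx)
    r = np.diff(L[0]) - seal.X @ beta
    W = seal.X[:, ds.re_idx]
    Vinv_o = np.linalg.inv(G) + W.T @ W / sigma2
    m_o = np.linalg.solve(Vinv_o, W.T @ r / sigma2)
    assert np.allclose(m, m_o, atol=1e-8)
    assert np.allclose(V, np.linalg.inv(Vinv_o), atol=1e-8)

    # huge prior scale: the conditional mean approaches the least-squares effect
    m_w, _ = gamma_conditional(seal, seal.X, L[0], beta, np.array([[1e8]]),
                               sigma2, ds.re_idx)
    ols = np.linalg.lstsq(W, r, rcond=None)[0]
    assert np.allclose(m_w, ols, atol=1e-5)


def test_G_conditional_inverse_wishart_update():
    prior = PriorConfig()
    gamma = np.array([[0.2], [-0.1], [0.4]])
    sc, df = G_conditional(gamma, prior)
    assert df == 1 + 1 + 3               # r0 = q+1, plus n individuals
    assert sc[0, 0] == pytest.approx(1.0 + float(np.sum(gamma ** 2)), abs=1e-12)


# ---------------------------------------------------------------------------
# bounded draws and kernel parity
# ---------------------------------------------------------------------------

def test_bounded_mvn_draw_respects_truncation():
    rng = np.random.default_rng(5)
    m = np.array([0.0, -0.5])
    V = np.array([[1.0, 0.3], [0.3, 0.5]])
    lo = np.array([-np.inf, 0.0])
    hi = np.array([np.inf, np.inf])
    cur = np.array([0.0, 0.1])
    draws = np.array([_draw_bounded_mvn(rng, m, V, lo, hi, cur)
                      for _ in range(10_000)])
    assert np.all(draws[:, 1] > 0)


def test_latent_kernel_parity_with_python_reference():
    """The compiled sweep and the pure-Python twin produce identical
    trajectories from identical random inputs."""
    rng = np.random.default_rng(6)
    T = 12
    L1 = 50.0 + np.cumsum(rng.normal(0, 1, T + 1))
    L2 = L1.copy()
    a = np.full(T, 0.995)
    c = rng.normal(0.2, 0.1, T)
    h = rng.integers(0, 5, T + 1).astype(float)
    obs = (h > 0).astype(np.uint8)
    D = np.where(h > 0, -0.3 + rng.normal(0, 0.1, T + 1), 0.0)
    R = np.full(T + 1, 300.0)
    nint = T - 1
    normals = rng.standard_normal(nint)
    uniforms = rng.random(nint)
    order = (rng.permutation(nint) + 1).astype(np.int64)
    args = (obs, D, h, R, -0.5, 1.2, 0.01, 4.0, 1.5, normals, uniforms, order)
    acc1 = latent_sweep(L1, a, c, *args)
    acc2 = latent_sweep_py(L2, a, c, *args)
    assert acc1 == acc2
    assert np.allclose(L1, L2, atol=1e-12)
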