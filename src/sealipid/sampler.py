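"""Metropolis-within-Gibbs sampler for parameters and latent lipid states.

Each sweep updates, in order: the latent lipid trajectories (single-site
random-walk Metropolis over a fresh random permutation of interior days,
endpoints fixed), the observation parameters alpha (conjugate bivariate
normal truncated to a positive slope), the fixed effects beta (conjugate
normal restricted to their bounds), the random effects gamma and their
covariance G (normal / inverse-Wishart), the variances tau2 and sigma2
(inverse gamma), and finally any missing covariates.

The beta, gamma and sigma2 conditionals are conjugate only when the
truncated-normal normaliser Phi(mu/sigma) is effectively 1 for every
transition.  The sampler monitors min(mu/sigma); above
``fast_path_threshold`` the conjugate draw is exact, otherwise the
conjugate draw becomes an independence Metropolis proposal whose
acceptance ratio is the exact product of truncation normalisers, so
correctness never depends on the data regime.

Conditional *moments* are exposed as plain functions so unit tests can
check them against independently coded conjugate algebra.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_ndtr, ndtri

from ._latent import latent_sweep, latent_chain
from .config import PriorConfig, SamplerConfig
from .likelihoods import ParameterState, log_prior
from .preprocessing import SealDataset

__all__ = [
    "PosteriorChains",
    "run_mcmc",
    "diagnostics",
    "sample_latent_fixed",
    "alpha_conditional",
    "beta_conditional",
    "tau2_conditional",
    "sigma2_conditional",
    "gamma_conditional",
    "G_conditional",
]


# ---------------------------------------------------------------------------
# conditional moments (pure functions; the oracle-testable algebra)
# ---------------------------------------------------------------------------

def _fill_latent(Xw, seal, L, latent_idx, latent_scale):
    if latent_idx is not None:
        m, s = latent_scale
        Xw[:, latent_idx] = (L[:-1] / seal.R[:-1] - m) / s


def _effective_coefs(beta, gamma_i, re_idx):
    eff = beta.copy()
    eff[re_idx] += gamma_i
    return eff


def _linear_coefs(seal, Xw, eff, latent_idx, latent_scale):
    """Per-day (a_t, c_t) with mu_t = a_t L_t + c_t for the kernel."""
    T = seal.T
    if latent_idx is None:
        a = np.ones(T)
        c = Xw @ eff
    else:
        m, s = latent_scale
        a = 1.0 + (eff[latent_idx] / s) / seal.R[:-1]
        c = Xw @ eff - eff[latent_idx] * Xw[:, latent_idx] - eff[latent_idx] * m / s
    return a, c


def _process_means(dataset, Xw_list, L_list, beta, gamma):
    """Current process means mu_{i,t} per seal (latent columns filled)."""
    mus = []
    for i, seal in enumerate(dataset.seals):
        eff = _effective_coefs(beta, gamma[i], dataset.re_idx)
        mus.append(L_list[i][:-1] + Xw_list[i] @ eff)
    return mus


def latent_gaussian_conditional(seal, a, c, alpha, tau2, sigma2):
    """Exact Gaussian full conditional of the interior days under the
    untruncated linear model, as (mean, banded precision, banded upper
    Cholesky).  Used by the block latent move and as the importance
    proposal in marginal-likelihood estimation."""
    from scipy.linalg import cholesky_banded, solveh_banded

    T = seal.T
    n = T - 1
    if n < 1:
        raise ValueError("no interior days")
    w = 1.0 / sigma2
    # transitions t -> t+1, t = 0..T-1; interior unknowns u_k = L_{k+1}
    const = -c.copy()
    const[T - 1] += seal.LT
    const[0] += -a[0] * seal.L0
    diag = w * (1.0 + a[1:] ** 2)
    b = w * (a[1:] * const[1:] - const[: T - 1])
    off = -w * a[1 : T - 1]
    tt = np.nonzero(seal.obs_mask)[0]
    tt = tt[(tt >= 1) & (tt <= T - 1)]
    if tt.size:
        wo = seal.h[tt] / tau2
        zc = alpha[1] / seal.R[tt]
        diag[tt - 1] += wo * zc * zc
        b[tt - 1] += wo * zc * (seal.D[tt] - alpha[0])
    ab = np.zeros((2, n))
    ab[0, 1:] = off
    ab[1] = diag
    mu = solveh_banded(ab, b, lower=False)
    U = cholesky_banded(ab, lower=False)
    return mu, ab, U


def _latent_block_update(seal, L, a, c, alpha, tau2, sigma2, rng):
    """Whole-trajectory independence-Metropolis update for one seal.

    The proposal is the exact Gaussian full conditional of the interior
    days under the *untruncated* linear model (the process mean is linear
    in L, so the Gaussian part of the acceptance ratio cancels exactly);
    acceptance corrects only for the truncated-normal normalisers and the
    L >= 0 support, so it is close to 1 away from the zero boundary.
    Returns True on acceptance (L modified in place).
    """
    from scipy.linalg import solve_banded

    T = seal.T
    if T - 1 < 1:
        return False
    sd = math.sqrt(sigma2)
    mu, _, U = latent_gaussian_conditional(seal, a, c, alpha, tau2, sigma2)
    z = rng.standard_normal(T - 1)
    prop_int = mu + solve_banded((0, 1), U, z)
    if np.any(prop_int < 0):
        return False
    mu_cur = a * L[:-1] + c
    Lp = L.copy()
    Lp[1:T] = prop_int
    mu_prop = a * Lp[:-1] + c
    lr = float(np.sum(log_ndtr(mu_cur / sd)) - np.sum(log_ndtr(mu_prop / sd)))
    if math.log(rng.random()) < lr:
        L[1:T] = prop_int
        return True
    return False


def alpha_conditional(dataset: SealDataset, L_list, tau2, prior: PriorConfig):
    """Mean and covariance of the conjugate alpha conditional.

    Weighted (weights h/tau2) linear regression of observed daily drift
    medians on the lipid:lean ratio, precision-blended with the prior.
    """
    zs, ds, ws = [], [], []
    for i, seal in enumerate(dataset.seals):
        m = seal.obs_mask
        if not m.any():
            continue
        zs.append(L_list[i][m] / seal.R[m])
        ds.append(seal.D[m])
        ws.append(seal.h[m] / tau2)
    if not zs:
        raise ValueError("no drift observations (all h are zero)")
    z = np.concatenate(zs)
    d = np.concatenate(ds)
    w = np.concatenate(ws)
    Z = np.column_stack([np.ones_like(z), z])
    a0 = np.asarray(prior.alpha_mean, dtype=float)
    A0inv = np.diag(1.0 / np.asarray(prior.alpha_var, dtype=float))
    Vinv = A0inv + Z.T @ (Z * w[:, None])
    rhs = A0inv @ a0 + Z.T @ (w * d)
    V = np.linalg.inv(Vinv)
    V = 0.5 * (V + V.T)
    return V @ rhs, V


def beta_conditional(dataset: SealDataset, Xw_list, L_list, gamma, sigma2,
                     prior: PriorConfig):
    """Mean and covariance of the (untruncated) beta conditional.

    Gaussian regression of daily lipid increments (random effects
    subtracted) on the design, under the optionally-proper normal prior.
    Raises on a singular design with a column diagnostic.
    """
    Xs, ys = [], []
    for i, seal in enumerate(dataset.seals):
        dL = np.diff(L_list[i])
        w_contrib = Xw_list[i][:, dataset.re_idx] @ gamma[i]
        Xs.append(Xw_list[i])
        ys.append(dL - w_contrib)
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    p = X.shape[1]
    XtX = X.T @ X
    if np.isfinite(prior.beta_prior_var):
        prior_prec = 1.0 / prior.beta_prior_var
    else:
        prior_prec = 0.0
    Vinv = XtX / sigma2 + prior_prec * np.eye(p)
    if prior_prec == 0.0:
        rank = np.linalg.matrix_rank(XtX)
        if rank < p:
            _, s, vt = np.linalg.svd(XtX)
            bad = [dataset.columns[j] for j in np.argsort(np.abs(vt[-1]))[::-1][:2]]
            raise np.linalg.LinAlgError(
                f"singular design (rank {rank} < {p}); suspect columns {bad}")
    rhs = X.T @ y / sigma2 + prior_prec * prior.beta_prior_mean * np.ones(p)
    V = np.linalg.inv(Vinv)
    V = 0.5 * (V + V.T)
    return V @ rhs, V


def tau2_conditional(dataset: SealDataset, L_list, alpha, prior: PriorConfig):
    """(shape, scale) of the exact inverse-gamma tau2 conditional."""
    a0, b0 = prior.inverse_gamma_hyper(prior.tau2_prior_mean, dataset.n_obs)
    ss = 0.0
    n = 0
    for i, seal in enumerate(dataset.seals):
        m = seal.obs_mask
        if not m.any():
            continue
        mu = alpha[0] + alpha[1] * L_list[i][m] / seal.R[m]
        ss += float(np.sum(seal.h[m] * (seal.D[m] - mu) ** 2))
        n += int(m.sum())
    return a0 + n / 2.0, b0 + ss / 2.0


def sigma2_conditional(dataset: SealDataset, mus, L_list, prior: PriorConfig):
    """(shape, scale) of the inverse-gamma sigma2 conditional (untruncated)."""
    a0, b0 = prior.inverse_gamma_hyper(prior.sigma2_prior_mean, dataset.n_transitions)
    ss = 0.0
    for i in range(len(L_list)):
        ss += float(np.sum((L_list[i][1:] - mus[i]) ** 2))
    return a0 + dataset.n_transitions / 2.0, b0 + ss / 2.0


def gamma_conditional(seal, Xw, L, beta, G, sigma2, re_idx):
    """Mean and covariance of one individual's random-effect conditional."""
    dL = np.diff(L)
    r = dL - Xw @ beta
    W = Xw[:, re_idx]
    Ginv = np.linalg.inv(G)
    Vinv = Ginv + W.T @ W / sigma2
    V = np.linalg.inv(Vinv)
    V = 0.5 * (V + V.T)
    return V @ (W.T @ r) / sigma2, V


def G_conditional(gamma, prior: PriorConfig):
    """(scale, df) of the inverse-Wishart conditional for G."""
    gam = np.atleast_2d(gamma)
    n, q = gam.shape
    R0 = np.asarray(prior.iw_scale, dtype=float) if prior.iw_scale is not None else np.eye(q)
    r0 = int(prior.iw_df) if prior.iw_df is not None else q + 1
    return R0 + gam.T @ gam, r0 + n


# ---------------------------------------------------------------------------
# draws
# ---------------------------------------------------------------------------

def _truncnorm_draw(rng, m, s, lo, hi):
    zlo = (lo - m) / s
    zhi = (hi - m) / s
    plo = stats.norm.cdf(zlo)
    phi_ = stats.norm.cdf(zhi)
    u = plo + rng.uniform() * (phi_ - plo)
    u = min(max(u, 1e-15), 1.0 - 1e-15)
    return m + s * ndtri(u)


def _draw_bounded_mvn(rng, m, V, lo, hi, current, cap=200):
    """Draw from N(m, V) restricted to a box.

    Rejection with a cap, then a one-scan coordinate-wise Gibbs fallback
    (inverse-CDF truncated normals) started from the current in-box value,
    which preserves the exact conditional as invariant distribution.
    """
    chol = np.linalg.cholesky(V)
    d = len(m)
    for _ in range(cap):
        x = m + chol @ rng.standard_normal(d)
        if np.all(x >= lo) and np.all(x <= hi):
            return x
    prec = np.linalg.inv(V)
    x = np.clip(current.astype(float).copy(), lo, hi)
    for j in range(d):
        vj = 1.0 / prec[j, j]
        r = prec[j] @ (x - m) - prec[j, j] * (x[j] - m[j])
        mj = m[j] - vj * r
        x[j] = _truncnorm_draw(rng, mj, math.sqrt(vj), lo[j], hi[j])
    return x


def _trunc_correction(mus_cur, mus_prop, sd_cur, sd_prop):
    """log MH ratio for an independence proposal from the untruncated
    conjugate conditional: sum log Phi(mu/sigma)_current - proposed."""
    s = 0.0
    for mc, mp in zip(mus_cur, mus_prop):
        s += float(np.sum(log_ndtr(mc / sd_cur)) - np.sum(log_ndtr(mp / sd_prop)))
    return s


def _min_mu_over_sigma(mus, sd):
    lo = math.inf
    for m in mus:
        if m.size:
            lo = min(lo, float(np.min(m)) / sd)
    return lo


# ---------------------------------------------------------------------------
# chains container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorChains:
    """Stored draws plus sampler metadata for one chain."""

    alpha: np.ndarray                 # (S, 2)
    beta: np.ndarray                  # (S, p)
    gamma: np.ndarray                 # (S, n_ind, q)
    tau2: np.ndarray                  # (S,)
    sigma2: np.ndarray                # (S,)
    G: np.ndarray                     # (S, q, q)
    latent: Optional[list]            # per seal (S, T+1) or None
    loglik: np.ndarray                # (S,) data log likelihood trace
    columns: list
    acceptance: dict
    seed: int
    config: dict
    dataset: SealDataset
    imputed: dict = field(default_factory=dict)   # (i, t, j) -> (S,) draws

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    def parameter_frame(self) -> pd.DataFrame:
        """Long (iteration, parameter, value) table of scalar parameters."""
        recs = {}
        recs["alpha1"], recs["alpha2"] = self.alpha[:, 0], self.alpha[:, 1]
        for j, c in enumerate(self.columns):
            recs[f"beta[{c}]"] = self.beta[:, j]
        recs["tau2"] = self.tau2
        recs["sigma2"] = self.sigma2
        q = self.G.shape[1]
        for j in range(q):
            for k in range(j, q):
                recs[f"G[{j},{k}]"] = self.G[:, j, k]
        df = pd.DataFrame(recs)
        df.insert(0, "iteration", np.arange(self.n_draws))
        return df.melt(id_vars="iteration", var_name="parameter", value_name="value")

    def scalar_draws(self) -> dict:
        """Named draw vectors for summarisation (standardised scale)."""
        out = {"alpha1": self.alpha[:, 0], "alpha2": self.alpha[:, 1]}
        for j, c in enumerate(self.columns):
            out[f"beta[{c}]"] = self.beta[:, j]
        out["tau2"] = self.tau2
        out["sigma2"] = self.sigma2
        return out

    def beta_original_scale(self) -> np.ndarray:
        """Beta draws back-transformed to the covariates' original units."""
        b = self.beta.copy()
        scaling = self.dataset.scaling
        cols = self.columns
        if "intercept" in cols:
            i0 = cols.index("intercept")
            for j, c in enumerate(cols):
                if c in scaling and j != i0:
                    m, s = scaling[c]
                    b[:, i0] -= b[:, j] * m / s
        for j, c in enumerate(cols):
            if c in scaling:
                _, s = scaling[c]
                b[:, j] = b[:, j] / s
        return b


def concat_chains(chains_list) -> "PosteriorChains":
    """Concatenate same-model chains (summaries are order-invariant)."""
    c0 = chains_list[0]
    latent = None
    if c0.latent is not None:
        latent = [np.concatenate([c.latent[i] for c in chains_list], axis=0)
                  for i in range(len(c0.latent))]
    imputed = {k: np.concatenate([c.imputed[k] for c in chains_list])
               for k in c0.imputed}
    return PosteriorChains(
        alpha=np.concatenate([c.alpha for c in chains_list]),
        beta=np.concatenate([c.beta for c in chains_list]),
        gamma=np.concatenate([c.gamma for c in chains_list]),
        tau2=np.concatenate([c.tau2 for c in chains_list]),
        sigma2=np.concatenate([c.sigma2 for c in chains_list]),
        G=np.concatenate([c.G for c in chains_list]),
        latent=latent,
        loglik=np.concatenate([c.loglik for c in chains_list]),
        columns=c0.columns, acceptance=c0.acceptance, seed=c0.seed,
        config=c0.config, dataset=c0.dataset, imputed=imputed)


# ---------------------------------------------------------------------------
# data log likelihood (for the trace and the divergence guard)
# ---------------------------------------------------------------------------

def data_loglik(dataset, Xw_list, L_list, state: ParameterState) -> float:
    """Joint log p(D, L, L_T | theta): observation terms plus truncated
    process transitions (including the final transition into the fixed
    arrival value)."""
    mus = _process_means(dataset, Xw_list, L_list, state.beta, state.gamma)
    sd = math.sqrt(state.sigma2)
    ll = 0.0
    for i, seal in enumerate(dataset.seals):
        m = seal.obs_mask
        if m.any():
            mu = state.alpha[0] + state.alpha[1] * L_list[i][m] / seal.R[m]
            var = state.tau2 / seal.h[m]
            ll += float(np.sum(-0.5 * (np.log(2 * np.pi * var)
                                       + (seal.D[m] - mu) ** 2 / var)))
        nxt = L_list[i][1:]
        ll += float(np.sum(-0.5 * (np.log(2 * np.pi * state.sigma2)
                                   + (nxt - mus[i]) ** 2 / state.sigma2)
                           - log_ndtr(mus[i] / sd)))
        if np.any(nxt < 0):
            return -np.inf
    return ll


# ---------------------------------------------------------------------------
# main sampler
# ---------------------------------------------------------------------------

def _initial_state(dataset, prior, rng) -> ParameterState:
    p, q, n = dataset.p, dataset.q, dataset.n_individuals
    bounds = _bounds_array(dataset)
    beta = np.clip(np.zeros(p), bounds[:, 0] + 1e-6, bounds[:, 1] - 1e-6)
    beta = np.where(np.isfinite(beta), beta, 0.0)
    alpha = np.array([prior.alpha_mean[0], max(prior.alpha_mean[1], 0.5)])
    return ParameterState(alpha=alpha, beta=beta, gamma=np.zeros((n, q)),
                          tau2=prior.tau2_prior_mean, sigma2=prior.sigma2_prior_mean,
                          G=0.1 * np.eye(q))


def _bounds_array(dataset) -> np.ndarray:
    b = np.full((dataset.p, 2), (-np.inf, np.inf))
    for name, (lo, hi) in dataset.spec.beta_bounds.items():
        if name in dataset.columns:
            j = dataset.columns.index(name)
            b[j] = (lo, hi)
    return b


def _covariate_imputation_setup(dataset):
    """Per-column Gaussian models fitted to the observed covariate values."""
    entries = []   # (seal index, t, column j)
    stats_ = {}
    for j in range(dataset.p):
        vals = []
        missing_any = False
        for i, seal in enumerate(dataset.seals):
            miss = seal.cov_missing[:, j]
            if miss.any():
                missing_any = True
                entries.extend((i, int(t), j) for t in np.nonzero(miss)[0])
            vals.append(seal.X[~miss, j])
        if missing_any:
            v = np.concatenate(vals)
            if v.size == 0:
                raise ValueError(f"covariate '{dataset.columns[j]}' entirely missing")
            stats_[j] = (float(v.mean()), float(v.var()) + 1e-12)
    return entries, stats_


def run_mcmc(dataset: SealDataset,
             prior_config: Optional[PriorConfig] = None,
             sampler_config: Optional[SamplerConfig] = None,
             fixed: Optional[dict] = None,
             init: Optional[ParameterState] = None) -> PosteriorChains:
    """Run one Metropolis-within-Gibbs chain.

    ``fixed`` maps block names ("latent", "alpha", "beta",
    "random_effects", "variances", "G") to values held constant -- used
    by reduced runs in Chib's marginal-likelihood decomposition and by
    fixed-parameter latent sampling.  Runs are bit-reproducible given the
    seed in ``sampler_config``.
    """
    prior = prior_config or PriorConfig()
    cfg = sampler_config or SamplerConfig()
    if cfg.seed is None:
        raise ValueError("a seed is mandatory for reproducibility")
    rng = np.random.default_rng(cfg.seed)
    fixed = fixed or {}

    n_iter = cfg.n_iterations
    burn = cfg.resolved_burnin()
    thin = max(cfg.thin, 1)
    keep = (n_iter - burn + thin - 1) // thin

    seals = dataset.seals
    n_ind, p, q = dataset.n_individuals, dataset.p, dataset.q
    li, lsc = dataset.latent_idx, dataset.latent_scale
    bounds = _bounds_array(dataset)

    state = (init or _initial_state(dataset, prior, rng)).copy()
    for key, attr in (("alpha", "alpha"), ("beta", "beta"), ("G", "G")):
        if key in fixed:
            setattr(state, attr, np.asarray(fixed[key], dtype=float).copy())
    if "variances" in fixed:
        state.tau2, state.sigma2 = (float(v) for v in fixed["variances"])
        fixed = {**fixed, "tau2": state.tau2, "sigma2": state.sigma2}
    if "tau2" in fixed:
        state.tau2 = float(fixed["tau2"])
    if "sigma2" in fixed:
        state.sigma2 = float(fixed["sigma2"])
    if "random_effects" in fixed:
        state.gamma = np.asarray(fixed["random_effects"], dtype=float).copy()

    L_list = ([np.asarray(v, dtype=float).copy() for v in fixed["latent"]]
              if "latent" in fixed else dataset.initial_latent())
    endpoints = [(Li[0], Li[-1]) for Li in L_list]
    Xw_list = [s.X.copy() for s in seals]
    for i, seal in enumerate(seals):
        _fill_latent(Xw_list[i], seal, L_list[i], li, lsc)

    imp_entries, imp_stats = _covariate_imputation_setup(dataset)
    imputed_draws = {e: np.empty(keep) for e in imp_entries}

    out = {
        "alpha": np.empty((keep, 2)), "beta": np.empty((keep, p)),
        "gamma": np.empty((keep, n_ind, q)), "tau2": np.empty(keep),
        "sigma2": np.empty(keep), "G": np.empty((keep, q, q)),
        "loglik": np.empty(keep),
    }
    latent_store = ([np.empty((keep, s.T + 1)) for s in seals]
                    if cfg.store_latent else None)

    prop_sd = cfg.latent_proposal_sd
    n_interior = sum(max(s.T - 1, 0) for s in seals)
    acc_counts = {"latent": 0, "latent_total": 0, "beta_mh": 0, "beta_mh_total": 0,
                  "sigma2_mh": 0, "sigma2_mh_total": 0, "gamma_mh": 0,
                  "gamma_mh_total": 0, "block": 0, "block_total": 0}
    thr = cfg.fast_path_threshold
    kidx = 0

    for it in range(n_iter):
        # --- latent states -------------------------------------------------
        if "latent" not in fixed:
            acc = 0
            for i, seal in enumerate(seals):
                T = seal.T
                if T < 2:
                    continue
                eff = _effective_coefs(state.beta, state.gamma[i], dataset.re_idx)
                a, c = _linear_coefs(seal, Xw_list[i], eff, li, lsc)
                nint = T - 1
                order = rng.permutation(nint) + 1
                normals = rng.standard_normal(nint)
                uniforms = rng.random(nint)
                acc += latent_sweep(L_list[i], a, c,
                                    seal.obs_mask.astype(np.uint8), np.nan_to_num(seal.D),
                                    seal.h.astype(np.float64), seal.R,
                                    state.alpha[0], state.alpha[1], state.tau2,
                                    state.sigma2, prop_sd, normals, uniforms,
                                    order.astype(np.int64))
                # whole-trajectory block move (exact linear-Gaussian
                # proposal); skipped if a latent-dependent column carries
                # a random effect, where the linearity breaks
                if li is None or li not in set(dataset.re_idx.tolist()):
                    acc_counts["block_total"] += 1
                    if _latent_block_update(seal, L_list[i], a, c, state.alpha,
                                            state.tau2, state.sigma2, rng):
                        acc_counts["block"] += 1
                _fill_latent(Xw_list[i], seal, L_list[i], li, lsc)
            acc_counts["latent"] += acc
            acc_counts["latent_total"] += n_interior
            if cfg.adapt and it < burn and n_interior:
                rate = acc / n_interior
                prop_sd = float(np.clip(prop_sd * math.exp(0.05 * (rate - 0.375)),
                                        1e-3, 50.0))

        sd = math.sqrt(state.sigma2)

        # --- alpha ---------------------------------------------------------
        if "alpha" not in fixed:
            m_a, V_a = alpha_conditional(dataset, L_list, state.tau2, prior)
            state.alpha = _draw_bounded_mvn(
                rng, m_a, V_a, np.array([-np.inf, 0.0]), np.array([np.inf, np.inf]),
                state.alpha)

        # --- beta ----------------------------------------------------------
        if "beta" not in fixed:
            m_b, V_b = beta_conditional(dataset, Xw_list, L_list, state.gamma,
                                        state.sigma2, prior)
            prop = _draw_bounded_mvn(rng, m_b, V_b, bounds[:, 0], bounds[:, 1],
                                     state.beta)
            mus_cur = _process_means(dataset, Xw_list, L_list, state.beta, state.gamma)
            if _min_mu_over_sigma(mus_cur, sd) > thr:
                state.beta = prop
            else:
                mus_prop = _process_means(dataset, Xw_list, L_list, prop, state.gamma)
                acc_counts["beta_mh_total"] += 1
                if math.log(rng.random()) < _trunc_correction(mus_cur, mus_prop, sd, sd):
                    state.beta = prop
                    acc_counts["beta_mh"] += 1

        # --- random effects and G ------------------------------------------
        if "random_effects" not in fixed:
            for i, seal in enumerate(seals):
                m_g, V_g = gamma_conditional(seal, Xw_list[i], L_list[i],
                                             state.beta, state.G, state.sigma2,
                                             dataset.re_idx)
                prop_g = m_g + np.linalg.cholesky(V_g) @ rng.standard_normal(q)
                eff_c = _effective_coefs(state.beta, state.gamma[i], dataset.re_idx)
                mu_c = L_list[i][:-1] + Xw_list[i] @ eff_c
                if float(np.min(mu_c, initial=np.inf)) / sd > thr:
                    state.gamma[i] = prop_g
                else:
                    eff_p = _effective_coefs(state.beta, prop_g, dataset.re_idx)
                    mu_p = L_list[i][:-1] + Xw_list[i] @ eff_p
                    acc_counts["gamma_mh_total"] += 1
                    if math.log(rng.random()) < _trunc_correction([mu_c], [mu_p], sd, sd):
                        state.gamma[i] = prop_g
                        acc_counts["gamma_mh"] += 1
            if "G" not in fixed:
                scale_G, df_G = G_conditional(state.gamma, prior)
                try:
                    state.G = stats.invwishart.rvs(df=df_G, scale=scale_G,
                                                   random_state=rng).reshape(q, q)
                except np.linalg.LinAlgError:
                    warnings.warn("non-PD inverse-Wishart scale; jittering")
                    scale_G = scale_G + 1e-8 * np.eye(q)
                    state.G = stats.invwishart.rvs(df=df_G, scale=scale_G,
                                                   random_state=rng).reshape(q, q)

        # --- variances -----------------------------------------------------
        if "tau2" not in fixed:
            sh_t, sc_t = tau2_conditional(dataset, L_list, state.alpha, prior)
            state.tau2 = float(stats.invgamma.rvs(sh_t, scale=sc_t, random_state=rng))
        if "sigma2" not in fixed:
            mus_cur = _process_means(dataset, Xw_list, L_list, state.beta, state.gamma)
            sh_s, sc_s = sigma2_conditional(dataset, mus_cur, L_list, prior)
            prop_s2 = float(stats.invgamma.rvs(sh_s, scale=sc_s, random_state=rng))
            if _min_mu_over_sigma(mus_cur, math.sqrt(prop_s2)) > thr and \
               _min_mu_over_sigma(mus_cur, math.sqrt(state.sigma2)) > thr:
                state.sigma2 = prop_s2
            else:
                acc_counts["sigma2_mh_total"] += 1
                lr = _trunc_correction(mus_cur, mus_cur, math.sqrt(state.sigma2),
                                       math.sqrt(prop_s2))
                if math.log(rng.random()) < lr:
                    state.sigma2 = prop_s2
                    acc_counts["sigma2_mh"] += 1

        # --- missing covariates ---------------------------------------------
        if imp_entries and "latent" not in fixed:
            _impute_covariates(dataset, Xw_list, L_list, state, imp_entries,
                               imp_stats, rng)

        # --- invariants, trace, storage --------------------------------------
        for i, Li in enumerate(L_list):
            assert Li[0] == endpoints[i][0] and Li[-1] == endpoints[i][1], \
                "fixed endpoints moved"
            assert np.all(Li >= 0), "negative latent lipid mass"
        np.linalg.cholesky(state.G + 1e-300 * np.eye(q))  # PD check

        if it >= burn and (it - burn) % thin == 0:
            ll = data_loglik(dataset, Xw_list, L_list, state)
            if not np.isfinite(ll):
                raise RuntimeError(
                    f"non-finite log likelihood at iteration {it}; state dump: "
                    f"alpha={state.alpha}, tau2={state.tau2}, sigma2={state.sigma2}")
            out["alpha"][kidx] = state.alpha
            out["beta"][kidx] = state.beta
            out["gamma"][kidx] = state.gamma
            out["tau2"][kidx] = state.tau2
            out["sigma2"][kidx] = state.sigma2
            out["G"][kidx] = state.G
            out["loglik"][kidx] = ll
            if latent_store is not None:
                for i in range(n_ind):
                    latent_store[i][kidx] = L_list[i]
            for e in imp_entries:
                i, t, j = e
                imputed_draws[e][kidx] = Xw_list[i][t, j]
            kidx += 1

    acceptance = {
        "latent": acc_counts["latent"] / max(acc_counts["latent_total"], 1),
        "latent_block": (acc_counts["block"] / acc_counts["block_total"]
                         if acc_counts["block_total"] else None),
        "latent_proposal_sd": prop_sd,
    }
    for key in ("beta", "sigma2", "gamma"):
        tot = acc_counts[f"{key}_mh_total"]
        acceptance[f"{key}_mh"] = acc_counts[f"{key}_mh"] / tot if tot else None

    return PosteriorChains(
        alpha=out["alpha"][:kidx], beta=out["beta"][:kidx],
        gamma=out["gamma"][:kidx], tau2=out["tau2"][:kidx],
        sigma2=out["sigma2"][:kidx], G=out["G"][:kidx],
        latent=[ls[:kidx] for ls in latent_store] if latent_store else None,
        loglik=out["loglik"][:kidx], columns=list(dataset.columns),
        acceptance=acceptance, seed=cfg.seed, config=cfg.to_dict(),
        dataset=dataset, imputed={e: v[:kidx] for e, v in imputed_draws.items()})


def _impute_covariates(dataset, Xw_list, L_list, state, entries, stats_, rng):
    """Draw missing continuous covariates from their full conditional:
    the fitted marginal Gaussian combined with the process-model term the
    covariate enters."""
    for (i, t, j) in entries:
        m0, v0 = stats_[j]
        eff = _effective_coefs(state.beta, state.gamma[i], dataset.re_idx)
        b = eff[j]
        seal = dataset.seals[i]
        Xw = Xw_list[i]
        mu_minus = (L_list[i][t] + Xw[t] @ eff - b * Xw[t, j])
        dL = L_list[i][t + 1]
        prec = 1.0 / v0 + b * b / state.sigma2
        mean = (m0 / v0 + b * (dL - mu_minus) / state.sigma2) / prec
        Xw[t, j] = mean + math.sqrt(1.0 / prec) * rng.standard_normal()


# ---------------------------------------------------------------------------
# fixed-parameter latent sampling (oracle comparisons, predictive checks)
# ---------------------------------------------------------------------------

def sample_latent_fixed(dataset: SealDataset, state: ParameterState,
                        n_sweeps: int, seed: int, seal_index: int = 0,
                        record_day: int = 1, proposal_sd: float = 0.5,
                        n_burnin: int = 0) -> np.ndarray:
    """Sample the latent trajectory of one seal with all parameters fixed.

    Returns the recorded day's value after every sweep (post burn-in).
    Used for grid-oracle comparisons and fixed-parameter studies.
    """
    rng = np.random.default_rng(seed)
    seal = dataset.seals[seal_index]
    li, lsc = dataset.latent_idx, dataset.latent_scale
    L = np.linspace(seal.L0, seal.LT, seal.T + 1)
    Xw = seal.X.copy()
    _fill_latent(Xw, seal, L, li, lsc)
    eff = _effective_coefs(state.beta, state.gamma[seal_index], dataset.re_idx)
    a, c = _linear_coefs(seal, Xw, eff, li, lsc)
    nint = seal.T - 1
    out_all = np.empty(0)
    chunk = 20000
    done = 0
    res = []
    while done < n_sweeps:
        k = min(chunk, n_sweeps - done)
        normals = rng.standard_normal((k, nint))
        uniforms = rng.random((k, nint))
        orders = np.empty((k, nint), dtype=np.int64)
        for s in range(k):
            orders[s] = rng.permutation(nint) + 1
        outbuf = np.empty(k)
        latent_chain(L, a, c, seal.obs_mask.astype(np.uint8), np.nan_to_num(seal.D),
                     seal.h.astype(np.float64), seal.R, state.alpha[0], state.alpha[1],
                     state.tau2, state.sigma2, proposal_sd, normals, uniforms,
                     orders, record_day, outbuf)
        res.append(outbuf)
        done += k
    out_all = np.concatenate(res)
    return out_all[n_burnin:]


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def diagnostics(chains_list) -> pd.DataFrame:
    """Effective sample size, split-R-hat and acceptance rates.

    Requires >= 2 chains for R-hat.  Returns a tidy frame with one row
    per scalar parameter.
    """
    import arviz as az

    if len(chains_list) < 2:
        raise ValueError("R-hat needs at least two chains")
    names = list(chains_list[0].scalar_draws().keys())
    stacked = {n: np.stack([c.scalar_draws()[n] for c in chains_list])
               for n in names}
    rows = []
    for n in names:
        arr = stacked[n]
        if np.allclose(arr.std(), 0):
            rhat, ess = 1.0, float("nan")
        else:
            rhat = float(np.asarray(
                az.rhat(az.convert_to_dataset(arr[..., None]))["x"].values).squeeze())
            ess = float(np.asarray(
                az.ess(az.convert_to_dataset(arr[..., None]))["x"].values).squeeze())
        rows.append({"parameter": n, "rhat": rhat, "ess": ess,
                     "flagged": bool(rhat > 1.05)})
    df = pd.DataFrame(rows)
    df.attrs["acceptance"] = [c.acceptance for c in chains_list]
    return df
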