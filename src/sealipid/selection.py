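"""Marginal-likelihood model comparison from Gibbs output (Chib's method).

The log marginal likelihood is assembled from the candidate's identity

    log m(y) = log p(y | theta*) + log p(theta*) - log p(theta* | y)

at an anchor point theta* = (alpha*, tau2*, sigma2*, G*) (default:
posterior means).  The posterior ordinate decomposes over the four
blocks, each estimated by averaging its full-conditional density at the
anchor over draws from a reduced Gibbs run in which the earlier blocks
are held fixed.  The high-dimensional quantities -- latent lipid
trajectories, random effects AND the fixed effects beta -- are not
ordinate blocks: they are integrated out of p(y | theta*).  Trajectories
are importance-sampled from the exact Gaussian posterior of the
untruncated linear state-space model (the process mean is linear in the
lipid mass, so this is closed form, with tridiagonal precision); given a
trajectory, (beta, gamma) enter the process mean linearly and are
integrated analytically under their Gaussian priors.  Estimating a
p-dimensional beta ordinate by averaging conditional densities is, by
contrast, badly behaved: the conditional mean moves with the latent
draws by many conditional standard deviations, so the log-mean-exp is
dominated by rare draws and systematically favours larger models.  The
analytic integration removes that term entirely.  Truncation enters as
(i) the per-transition normalisers evaluated at the conditional mean of
(beta, gamma) -- exact in the negligible-truncation regime the sampler
monitors -- and (ii) an exact bound-mass correction for box-truncated
beta priors with a single bounded coordinate.

Monte-Carlo standard errors use batch means (20 batches).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import log_ndtr, logsumexp

from .config import ModelCandidate, PriorConfig, SamplerConfig
from .likelihoods import ParameterState
from .preprocessing import SealDataset, build_dataset
from .sampler import (PosteriorChains, run_mcmc, alpha_conditional,
                      tau2_conditional, sigma2_conditional,
                      G_conditional, _bounds_array, _effective_coefs,
                      _fill_latent, _linear_coefs, latent_gaussian_conditional)

__all__ = ["ChibResult", "chib_log_marginal", "compare_models",
           "log_mean_exp", "ordinate_from_draws", "chib_assemble",
           "integrated_loglik", "evidence_given_anchor"]


def log_mean_exp(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(logsumexp(x) - math.log(len(x)))


def ordinate_from_draws(log_densities, n_batches: int = 20) -> tuple:
    """Average a full-conditional density over posterior draws.

    Returns (log ordinate, standard error of the log) with the standard
    error from batch means.
    """
    lv = np.asarray(log_densities, dtype=float)
    overall = log_mean_exp(lv)
    nb = min(n_batches, max(len(lv) // 2, 1))
    batches = np.array_split(lv, nb)
    bm = np.array([log_mean_exp(b) for b in batches])
    se = float(np.std(np.exp(bm - overall), ddof=1) / math.sqrt(nb)) if nb > 1 else np.nan
    return overall, se


@dataclass
class ChibResult:
    """One model's estimated log marginal likelihood."""

    log_marginal: float
    se: float
    loglik_at_anchor: float
    log_prior_at_anchor: float
    log_ordinates: dict = field(default_factory=dict)
    anchor: Optional[ParameterState] = None

    def __repr__(self):
        return (f"ChibResult(log_marginal={self.log_marginal:.3f}, "
                f"se={self.se:.3f})")


def chib_assemble(loglik: float, logprior: float, ordinates: dict) -> ChibResult:
    """Combine the three terms of the candidate's identity; ordinate
    standard errors add in quadrature on the log scale."""
    total_ord = sum(v[0] for v in ordinates.values())
    se = math.sqrt(sum((v[1] if np.isfinite(v[1]) else 0.0) ** 2
                       for v in ordinates.values()))
    return ChibResult(log_marginal=loglik + logprior - total_ord, se=se,
                      loglik_at_anchor=loglik, log_prior_at_anchor=logprior,
                      log_ordinates=dict(ordinates))


# ---------------------------------------------------------------------------
# latent-integrated likelihood at the anchor
# ---------------------------------------------------------------------------

def _seal_loglik_is(dataset: SealDataset, i: int, state: ParameterState,
                    rng: np.random.Generator, n_draws: int) -> tuple:
    """log p(D_i, L_{i,T} | L_{i,0}, theta*) for one individual.

    Builds the exact Gaussian posterior of (interior L, gamma_i) under
    the untruncated linear model, computes its marginal evidence in
    closed form, and corrects by importance sampling for the truncation
    terms.  Returns (log likelihood, IS standard error of the log).
    """
    seal = dataset.seals[i]
    T = seal.T
    q = dataset.q
    li, (mll, sll) = dataset.latent_idx, dataset.latent_scale
    alpha, beta = state.alpha, state.beta
    tau2, sigma2 = state.tau2, state.sigma2
    sd = math.sqrt(sigma2)

    # reference fill for any latent-dependent random-effect column
    Lref = np.linspace(seal.L0, seal.LT, T + 1)
    Xref = seal.X.copy()
    if li is not None:
        Xref[:, li] = (Lref[:-1] / seal.R[:-1] - mll) / sll

    # unknowns u = (L_1..L_{T-1}, gamma); linear coefficients of mu_t
    d = (T - 1) + q
    Q = np.zeros((d, d))
    b = np.zeros(d)
    const = 0.0

    def add_term(s0, svec, w):
        nonlocal const
        nonlocal Q, b
        Q += w * np.outer(svec, svec)
        b += -w * s0 * svec
        const += -0.5 * w * s0 * s0 - 0.5 * math.log(2.0 * math.pi / w)

    # gamma prior
    Ginv = np.linalg.inv(state.G)
    Q[T - 1:, T - 1:] += Ginv
    sign, logdetG = np.linalg.slogdet(state.G)
    const += -0.5 * (q * math.log(2 * math.pi) + logdetG)

    if li is not None:
        a_coef = 1.0 + (beta[li] / sll) / seal.R[:-1]
        c_base = Xref @ beta - beta[li] * Xref[:, li] - beta[li] * mll / sll
    else:
        a_coef = np.ones(T)
        c_base = Xref @ beta
    W = Xref[:, dataset.re_idx]    # (T, q) random-effect rows

    def uvec(tidx=None, coefL=0.0, gam=None):
        v = np.zeros(d)
        if tidx is not None and 1 <= tidx <= T - 1:
            v[tidx - 1] = coefL
        if gam is not None:
            v[T - 1:] += gam
        return v

    # transitions t -> t+1: residual L_{t+1} - a_t L_t - c_t - w_t gamma
    for t in range(T):
        s0 = -c_base[t]
        svec = uvec(gam=-W[t])
        if t + 1 <= T - 1:
            svec += uvec(t + 1, 1.0)
        else:
            s0 += seal.LT
        if 1 <= t <= T - 1:
            svec += uvec(t, -a_coef[t])
        else:
            s0 += -a_coef[t] * seal.L0
        add_term(s0, svec, 1.0 / sigma2)

    # observations
    for t in np.nonzero(seal.obs_mask)[0]:
        w = seal.h[t] / tau2
        zcoef = alpha[1] / seal.R[t]
        if 1 <= t <= T - 1:
            add_term(seal.D[t] - alpha[0], -uvec(t, zcoef), w)
        else:
            Lt = seal.L0 if t == 0 else seal.LT
            resid = seal.D[t] - alpha[0] - zcoef * Lt
            const += -0.5 * w * resid * resid - 0.5 * math.log(2 * math.pi / w)

    cF, low = cho_factor(Q, lower=True)
    mu_u = cho_solve((cF, low), b)
    logdetQ = 2.0 * float(np.sum(np.log(np.diag(cF))))
    quad_mu = float(-0.5 * mu_u @ Q @ mu_u + b @ mu_u)
    log_linear_evidence = quad_mu + const - 0.5 * logdetQ + 0.5 * d * math.log(2 * math.pi)

    # importance-sample the truncation correction
    z = rng.standard_normal((n_draws, d))
    U = mu_u + solve_triangular(cF, z.T, lower=True, trans="T").T
    logw = np.empty(n_draws)
    for s in range(n_draws):
        u = U[s]
        L = np.empty(T + 1)
        L[0], L[-1] = seal.L0, seal.LT
        L[1:T] = u[: T - 1]
        if np.any(L < 0):
            logw[s] = -np.inf
            continue
        gam = u[T - 1:]
        Xs = seal.X.copy()
        if li is not None:
            Xs[:, li] = (L[:-1] / seal.R[:-1] - mll) / sll
        eff = _effective_coefs(beta, gam, dataset.re_idx)
        mus = L[:-1] + Xs @ eff
        # exact - linear reduces to the truncation normalisers (the mean is
        # exactly linear in L unless a latent-dependent column carries a
        # random effect, in which case the residual difference enters too)
        logw[s] = -float(np.sum(log_ndtr(mus / sd)))
        if li is not None and li in set(dataset.re_idx.tolist()):
            mus_lin = a_coef * L[:-1] + c_base + W @ gam
            logw[s] += float(np.sum(-0.5 * ((L[1:] - mus) ** 2
                                            - (L[1:] - mus_lin) ** 2) / sigma2))
    corr = log_mean_exp(logw)
    wts = np.exp(logw - np.max(logw[np.isfinite(logw)]))
    ess = wts.sum() ** 2 / np.sum(wts ** 2)
    se = float(np.std(wts / wts.mean(), ddof=1) / math.sqrt(n_draws)) if n_draws > 1 else np.nan
    return log_linear_evidence + corr, se, ess


def integrated_loglik(dataset: SealDataset, state: ParameterState,
                      n_draws: int = 400, seed: int = 0) -> tuple:
    """Latent- and random-effect-integrated log p(y | theta) at *fixed*
    beta, summed over individuals; returns (loglik, se).  Used for
    likelihood diagnostics at a full parameter state."""
    rng = np.random.default_rng(seed)
    total, var = 0.0, 0.0
    for i in range(dataset.n_individuals):
        ll, se, _ = _seal_loglik_is(dataset, i, state, rng, n_draws)
        total += ll
        var += se ** 2 if np.isfinite(se) else 0.0
    return total, math.sqrt(var)


def evidence_given_anchor(dataset: SealDataset, anchor: ParameterState,
                          prior: PriorConfig, n_draws: int = 300,
                          seed: int = 0) -> tuple:
    """log p(y | alpha*, tau2*, sigma2*, G*): latent trajectories by
    importance sampling, (beta, gamma) integrated analytically.

    Trajectory proposals are the exact Gaussian conditionals of the
    untruncated linear model linearised at the anchor's beta/gamma.
    Given a trajectory set, daily increments are linear in (beta,
    gamma_1..gamma_n), whose Gaussian priors (beta ~ N(mean, B I),
    gamma_i ~ N(0, G*)) integrate in closed form.  Truncation enters via
    the per-transition normalisers at the conditional mean and an exact
    bound-mass ratio for box-truncated beta coordinates.  Returns
    (log evidence, importance-sampling standard error of the log).
    """
    from scipy.linalg import solve_banded

    if not np.isfinite(prior.beta_prior_var):
        raise ValueError("marginal likelihood is undefined under an improper "
                         "(flat) beta prior; set a finite beta_prior_var")
    rng = np.random.default_rng(seed)
    seals = dataset.seals
    n_ind, p, q = dataset.n_individuals, dataset.p, dataset.q
    li, lsc = dataset.latent_idx, dataset.latent_scale
    sigma2, tau2, alpha = anchor.sigma2, anchor.tau2, anchor.alpha
    sd = math.sqrt(sigma2)
    bounds = _bounds_array(dataset)
    d = p + n_ind * q
    n_trans = dataset.n_transitions

    # prior over v = (beta, gamma_1..gamma_n)
    v0 = np.zeros(d)
    v0[:p] = prior.beta_prior_mean
    P0inv = np.zeros((d, d))
    P0inv[:p, :p] = np.eye(p) / prior.beta_prior_var
    Ginv = np.linalg.inv(anchor.G)
    for i in range(n_ind):
        sl_ = slice(p + i * q, p + (i + 1) * q)
        P0inv[sl_, sl_] = Ginv
    sign, logdet_P0inv = np.linalg.slogdet(P0inv)
    log_prior_norm = 0.5 * logdet_P0inv - 0.5 * d * math.log(2 * math.pi)
    # bound mass of the truncated beta prior
    prior_sd = math.sqrt(prior.beta_prior_var)
    log_prior_bound_mass = 0.0
    bounded = [j for j in range(p)
               if np.isfinite(bounds[j, 0]) or np.isfinite(bounds[j, 1])]
    for j in bounded:
        zlo = (bounds[j, 0] - prior.beta_prior_mean) / prior_sd
        zhi = (bounds[j, 1] - prior.beta_prior_mean) / prior_sd
        log_prior_bound_mass += math.log(stats.norm.cdf(zhi) - stats.norm.cdf(zlo))

    # per-seal proposals at the anchor, plus fixed observation pieces
    props = []
    for i, seal in enumerate(seals):
        eff = _effective_coefs(anchor.beta, anchor.gamma[i], dataset.re_idx)
        Xw = seal.X.copy()
        _fill_latent(Xw, seal, np.linspace(seal.L0, seal.LT, seal.T + 1), li, lsc)
        a, c = _linear_coefs(seal, Xw, eff, li, lsc)
        mu, ab, U = latent_gaussian_conditional(seal, a, c, alpha, tau2, sigma2)
        logdetQ = 2.0 * float(np.sum(np.log(U[1])))
        props.append((mu, ab, U, logdetQ))

    logw = np.empty(n_draws)
    for s in range(n_draws):
        Ls, logq = [], 0.0
        ok = True
        for i, seal in enumerate(seals):
            mu, ab, U, logdetQ = props[i]
            n_i = seal.T - 1
            z = rng.standard_normal(n_i)
            Lint = mu + solve_banded((0, 1), U, z)
            if np.any(Lint < 0):
                ok = False
                break
            L = np.empty(seal.T + 1)
            L[0], L[-1] = seal.L0, seal.LT
            L[1:-1] = Lint
            Ls.append(L)
            ddev = Lint - mu
            quad = (ab[1] * ddev * ddev).sum() + 2.0 * (ab[0, 1:] * ddev[:-1]
                                                        * ddev[1:]).sum()
            logq += 0.5 * logdetQ - 0.5 * n_i * math.log(2 * math.pi) - 0.5 * quad
        if not ok:
            logw[s] = -np.inf
            continue

        # analytic (beta, gamma) integral given the trajectories
        Q = P0inv.copy()
        b = P0inv @ v0
        yy = 0.0
        obs_ll = 0.0
        rows_mu_parts = []
        for i, seal in enumerate(seals):
            L = Ls[i]
            Xs = seal.X.copy()
            _fill_latent(Xs, seal, L, li, lsc)
            A_i = np.zeros((seal.T, d))
            A_i[:, :p] = Xs
            A_i[:, p + i * q: p + (i + 1) * q] = Xs[:, dataset.re_idx]
            y_i = np.diff(L)
            Q += A_i.T @ A_i / sigma2
            b += A_i.T @ y_i / sigma2
            yy += float(y_i @ y_i)
            m = seal.obs_mask
            if m.any():
                muo = alpha[0] + alpha[1] * L[m] / seal.R[m]
                var = tau2 / seal.h[m]
                obs_ll += float(np.sum(-0.5 * (np.log(2 * np.pi * var)
                                               + (seal.D[m] - muo) ** 2 / var)))
            rows_mu_parts.append((A_i, y_i))
        cF = np.linalg.cholesky(Q)
        half = np.linalg.solve(cF, b)
        vhat = np.linalg.solve(cF.T, half)
        logdetQv = 2.0 * float(np.sum(np.log(np.diag(cF))))
        log_evidence_lin = (-0.5 * n_trans * math.log(2 * math.pi * sigma2)
                            - 0.5 * yy / sigma2
                            + 0.5 * float(half @ half)
                            - 0.5 * float((v0 @ (P0inv @ v0)))
                            - 0.5 * logdetQv + 0.5 * d * math.log(2 * math.pi)
                            + log_prior_norm)
        # truncation normalisers at the conditional mean of (beta, gamma)
        trunc = 0.0
        for i, seal in enumerate(seals):
            A_i, y_i = rows_mu_parts[i]
            mus = Ls[i][:-1] + A_i @ vhat
            trunc -= float(np.sum(log_ndtr(mus / sd)))
        # beta bound mass: posterior (given L) over prior
        post_bound = 0.0
        Vd = None
        for j in bounded:
            if Vd is None:
                Vd = np.linalg.inv(Q)
            sj = math.sqrt(Vd[j, j])
            post_bound += math.log(max(
                stats.norm.cdf((bounds[j, 1] - vhat[j]) / sj)
                - stats.norm.cdf((bounds[j, 0] - vhat[j]) / sj), 1e-300))
        logw[s] = (obs_ll + log_evidence_lin + trunc + post_bound
                   - log_prior_bound_mass - logq)

    finite = logw[np.isfinite(logw)]
    if finite.size == 0:
        raise FloatingPointError("all importance weights degenerate")
    total = log_mean_exp(logw)   # -inf entries count as zero weight
    wts = np.exp(logw - np.max(finite))
    wts[~np.isfinite(wts)] = 0.0
    se = float(np.std(wts / wts.mean(), ddof=1) / math.sqrt(len(logw)))
    return total, se


# ---------------------------------------------------------------------------
# block ordinates
# ---------------------------------------------------------------------------

def _trunc_mvn_logpdf(x, m, V, lo, hi) -> float:
    """Log density of N(m, V) restricted to a box, at an in-box point."""
    lp = float(stats.multivariate_normal.logpdf(x, m, V, allow_singular=True))
    bounded = [j for j in range(len(m)) if np.isfinite(lo[j]) or np.isfinite(hi[j])]
    if not bounded:
        return lp
    if len(bounded) == 1:
        j = bounded[0]
        s = math.sqrt(V[j, j])
        mass = (stats.norm.cdf((hi[j] - m[j]) / s)
                - stats.norm.cdf((lo[j] - m[j]) / s))
    else:
        sub = np.ix_(bounded, bounded)
        mvn = stats.multivariate_normal(mean=np.asarray(m)[bounded], cov=V[sub])
        mass = float(mvn.cdf(np.asarray(hi)[bounded],
                             lower_limit=np.asarray(lo)[bounded]))
    return lp - math.log(max(mass, 1e-300))


def _anchor_from_chains(chains: PosteriorChains, bounds) -> ParameterState:
    beta = chains.beta.mean(axis=0)
    beta = np.clip(beta, bounds[:, 0] + 1e-9, bounds[:, 1] - 1e-9)
    return ParameterState(
        alpha=chains.alpha.mean(axis=0),
        beta=beta,
        gamma=chains.gamma.mean(axis=0),
        tau2=float(chains.tau2.mean()),
        sigma2=float(chains.sigma2.mean()),
        G=chains.G.mean(axis=0))


def _subsample(n, cap, rng):
    if n <= cap:
        return np.arange(n)
    return np.sort(rng.choice(n, size=cap, replace=False))


def chib_log_marginal(chains: PosteriorChains,
                      dataset: SealDataset,
                      prior_config: Optional[PriorConfig] = None,
                      anchor: Optional[ParameterState] = None,
                      reduced_config: Optional[SamplerConfig] = None,
                      n_is_draws: int = 300,
                      ordinate_cap: int = 400,
                      seed: Optional[int] = None) -> ChibResult:
    """Estimate log m(y) for the fitted model behind ``chains``.

    ``reduced_config`` sets the length of the four reduced Gibbs runs
    (default: the main run's settings).  The main chains must contain
    stored latent draws.
    """
    if chains.latent is None:
        raise ValueError("Chib's decomposition needs stored latent draws")
    prior = prior_config or PriorConfig()
    bounds = _bounds_array(dataset)
    theta = anchor or _anchor_from_chains(chains, bounds)
    base_seed = int(seed if seed is not None else (chains.seed * 7 + 11) % (2 ** 31))
    rng = np.random.default_rng(base_seed)

    cfg0 = reduced_config or SamplerConfig(**{**chains.config})
    ordinates = {}

    def conditional_draws(ch, fn):
        idx = _subsample(ch.n_draws, ordinate_cap, rng)
        vals = np.empty(len(idx))
        for k, g in enumerate(idx):
            L_g = [ch.latent[i][g] for i in range(dataset.n_individuals)]
            vals[k] = fn(ch, g, L_g)
        return vals

    # block 1: alpha, from the main run
    def alpha_logpdf(ch, g, L_g):
        m, V = alpha_conditional(dataset, L_g, ch.tau2[g], prior)
        return _trunc_mvn_logpdf(theta.alpha, m, V,
                                 np.array([-np.inf, 0.0]), np.array([np.inf, np.inf]))
    ordinates["alpha"] = ordinate_from_draws(conditional_draws(chains, alpha_logpdf))

    def reduced(fixed, k):
        cfg = SamplerConfig(**{**cfg0.to_dict(),
                               "seed": (base_seed + 101 * k) % (2 ** 31),
                               "store_latent": True})
        return run_mcmc(dataset, prior, cfg, fixed=fixed)

    # block 2: tau2 | alpha*
    ch1 = reduced({"alpha": theta.alpha}, 1)
    def tau2_logpdf(ch, g, L_g):
        sh, sc = tau2_conditional(dataset, L_g, theta.alpha, prior)
        return float(stats.invgamma.logpdf(theta.tau2, sh, scale=sc))
    ordinates["tau2"] = ordinate_from_draws(conditional_draws(ch1, tau2_logpdf))

    # block 3: sigma2 | alpha*, tau2* (beta and gamma remain sampled; the
    # ordinate averages over their reduced-run posterior)
    ch2 = reduced({"alpha": theta.alpha, "tau2": theta.tau2}, 2)
    def sigma2_logpdf(ch, g, L_g):
        Xw = []
        for i, seal in enumerate(dataset.seals):
            Xi = seal.X.copy()
            _fill_latent(Xi, seal, L_g[i], dataset.latent_idx, dataset.latent_scale)
            Xw.append(Xi)
        mus = [L_g[i][:-1] + Xw[i] @ _effective_coefs(ch.beta[g], ch.gamma[g][i],
                                                      dataset.re_idx)
               for i in range(dataset.n_individuals)]
        sh, sc = sigma2_conditional(dataset, mus, L_g, prior)
        return float(stats.invgamma.logpdf(theta.sigma2, sh, scale=sc))
    ordinates["sigma2"] = ordinate_from_draws(conditional_draws(ch2, sigma2_logpdf))

    # block 4: G | alpha*, tau2*, sigma2*
    ch3 = reduced({"alpha": theta.alpha, "tau2": theta.tau2,
                   "sigma2": theta.sigma2}, 3)
    def G_logpdf(ch, g, L_g):
        sc, df = G_conditional(ch.gamma[g], prior)
        return float(stats.invwishart.logpdf(theta.G, df=df, scale=sc))
    ordinates["G"] = ordinate_from_draws(conditional_draws(ch3, G_logpdf))

    for k, v in ordinates.items():
        if not np.isfinite(v[0]):
            raise FloatingPointError(f"non-finite posterior ordinate in block '{k}'")

    loglik, ll_se = evidence_given_anchor(dataset, theta, prior,
                                          n_draws=n_is_draws,
                                          seed=(base_seed + 977) % (2 ** 31))
    lp = _log_prior_theta(theta, prior, dataset)
    res = chib_assemble(loglik, lp, ordinates)
    res.se = math.sqrt(res.se ** 2 + ll_se ** 2)
    res.anchor = theta
    return res


def _log_prior_theta(theta: ParameterState, prior: PriorConfig,
                     dataset: SealDataset) -> float:
    """Prior density of the ordinate blocks (alpha, tau2, sigma2, G)
    only; beta and the random effects are integrated into the
    likelihood term."""
    m = np.asarray(prior.alpha_mean, dtype=float)
    v = np.asarray(prior.alpha_var, dtype=float)
    if theta.alpha[1] <= 0:
        return -np.inf
    lp = float(np.sum(stats.norm.logpdf(theta.alpha, m, np.sqrt(v))))
    lp -= float(stats.norm.logcdf(m[1] / math.sqrt(v[1])))
    at, bt = prior.inverse_gamma_hyper(prior.tau2_prior_mean, dataset.n_obs)
    asg, bsg = prior.inverse_gamma_hyper(prior.sigma2_prior_mean,
                                         dataset.n_transitions)
    lp += float(stats.invgamma.logpdf(theta.tau2, at, scale=bt))
    lp += float(stats.invgamma.logpdf(theta.sigma2, asg, scale=bsg))
    q = theta.G.shape[0]
    scale = (np.asarray(prior.iw_scale, dtype=float)
             if prior.iw_scale is not None else np.eye(q))
    df = int(prior.iw_df) if prior.iw_df is not None else q + 1
    lp += float(stats.invwishart.logpdf(theta.G, df=df, scale=scale))
    return lp


# ---------------------------------------------------------------------------
# candidate comparison
# ---------------------------------------------------------------------------

def compare_models(track_days: pd.DataFrame,
                   drift: pd.DataFrame,
                   physiology: Sequence,
                   candidates: Sequence[ModelCandidate],
                   prior_config: Optional[PriorConfig] = None,
                   sampler_config: Optional[SamplerConfig] = None,
                   reduced_config: Optional[SamplerConfig] = None,
                   n_is_draws: int = 300) -> pd.DataFrame:
    """Fit each candidate and rank by estimated log marginal likelihood.

    A candidate whose fit or estimate fails is marked failed and the
    comparison proceeds.  Returns a frame sorted best-first with the
    winner flagged.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    cfg = sampler_config or SamplerConfig(seed=0)
    rows = []
    for k, cand in enumerate(candidates):
        prior = cand.prior_config or prior_config or PriorConfig()
        try:
            dataset = build_dataset(track_days, drift, physiology, cand.model_spec)
            ccfg = SamplerConfig(**{**cfg.to_dict(),
                                    "seed": (cfg.seed + 31 * k) % (2 ** 31),
                                    "store_latent": True})
            chains = run_mcmc(dataset, prior, ccfg)
            res = chib_log_marginal(chains, dataset, prior,
                                    reduced_config=reduced_config,
                                    n_is_draws=n_is_draws)
            rows.append({"label": cand.label, "non_lipid_form": cand.non_lipid_form,
                         "log_marginal": res.log_marginal, "se": res.se,
                         "failed": False})
        except Exception as exc:  # noqa: BLE001 - candidate-level robustness
            rows.append({"label": cand.label, "non_lipid_form": cand.non_lipid_form,
                         "log_marginal": -np.inf, "se": np.nan, "failed": True,
                         "error": str(exc)})
    df = pd.DataFrame(rows).sort_values("log_marginal", ascending=False,
                                        ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["winner"] = df["rank"] == 1
    return df
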