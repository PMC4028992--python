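"""Densities and priors of the hierarchical drift-dive / lipid model.

Observation model
    D_t ~ Normal(alpha1 + alpha2 * L_t / R_t,  tau2 / h_t)       (h_t >= 1)
where D_t is the median daily drift rate, L_t the latent lipid mass,
R_t the fixed non-lipid tissue mass and h_t the number of drift dives
that day: more drift dives give a more precise daily median.

Process model
    L_{t+1} ~ Normal_+(L_t + x_t beta + w_t gamma_i,  sigma2)
a zero-truncated normal on the daily lipid increment, with covariates
x_t (one column of which -- the lipid:lean ratio L_t/R_t -- depends on
the latent state itself) and q < p individual random effects gamma_i.

Parameter models: truncated bivariate normal on alpha (positive slope),
informative inverse-gamma priors on tau2 / sigma2 whose prior means match
the error ceilings (0.1 m/s drift error, 2 kg/day lipid error) weighted
proportional to sample size, independent (optionally flat) truncated
normals on beta, IW(diag(1,q), q+1) on the random-effects covariance G
and gamma_i ~ N(0, G).

All functions are pure and finite on their support, -inf exactly off it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import log_ndtr

from .config import PriorConfig

__all__ = [
    "ParameterState",
    "obs_mean",
    "obs_loglik",
    "process_mean",
    "process_logdensity",
    "log_prior",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class ParameterState:
    """One draw of all model parameters."""

    alpha: np.ndarray   # (2,) observation intercept and slope (m/s units)
    beta: np.ndarray    # (p,) fixed effects, kg/day per covariate unit
    gamma: np.ndarray   # (n_individuals, q) random effects, kg/day
    tau2: float         # observation variance, (m/s)^2
    sigma2: float       # process variance, kg^2
    G: np.ndarray       # (q, q) random-effects covariance

    def copy(self) -> "ParameterState":
        return ParameterState(self.alpha.copy(), self.beta.copy(), self.gamma.copy(),
                              float(self.tau2), float(self.sigma2), self.G.copy())


def obs_mean(L_t, R_t, alpha):
    """Expected drift rate alpha1 + alpha2 * (L_t / R_t)."""
    L_t = np.asarray(L_t, dtype=float)
    R_t = np.asarray(R_t, dtype=float)
    if np.any(R_t <= 0):
        raise ValueError("non-lipid tissue R_t must be positive")
    return alpha[0] + alpha[1] * (L_t / R_t)


def obs_loglik(D_t, h_t, L_t, R_t, alpha, tau2):
    """Gaussian log density of the median drift rate, variance tau2 / h_t.

    Days without drift dives (h_t = 0) carry no observation; callers must
    skip them, so h_t = 0 here is a contract violation.
    """
    h_t = np.asarray(h_t, dtype=float)
    if np.any(h_t < 1):
        raise ValueError("obs_loglik requires h_t >= 1; skip h == 0 days")
    mu = obs_mean(L_t, R_t, alpha)
    var = tau2 / h_t
    D_t = np.asarray(D_t, dtype=float)
    return -0.5 * (_LOG2PI + np.log(var) + (D_t - mu) ** 2 / var)


def process_mean(L_t, x_t, beta, w_t=None, gamma_i=None):
    """Mean of tomorrow's lipid mass: L_t + x_t beta (+ w_t gamma_i).

    ``x_t``'s latent-dependent column must already be filled from the
    current L_t (lipid:lean ratio = L_t / R_t, on the design's scale).
    """
    m = np.asarray(L_t, dtype=float) + np.dot(np.asarray(x_t, dtype=float), beta)
    if w_t is not None and gamma_i is not None:
        m = m + np.dot(np.asarray(w_t, dtype=float), gamma_i)
    return m


def process_logdensity(L_next, mean, sigma2):
    """Log density of the zero-truncated normal lipid transition.

    log N(L_next; mean, sigma2) - log Phi(mean / sigma) for L_next >= 0,
    -inf below zero.  Vectorised over ``L_next`` and ``mean``.
    """
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    L_next = np.asarray(L_next, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = math.sqrt(sigma2)
    out = (-0.5 * (_LOG2PI + math.log(sigma2) + (L_next - mean) ** 2 / sigma2)
           - log_ndtr(mean / sd))
    out = np.where(L_next < 0, -np.inf, out)
    if out.ndim == 0:
        return float(out)
    return out


def _beta_log_prior(beta, bounds, prior: PriorConfig):
    """Independent (truncated) normal or flat-with-bounds prior on beta."""
    beta = np.asarray(beta, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(beta < lo) or np.any(beta > hi):
        return -np.inf
    if not np.isfinite(prior.beta_prior_var):
        return 0.0  # improper flat within bounds
    sd = math.sqrt(prior.beta_prior_var)
    lp = stats.norm.logpdf(beta, prior.beta_prior_mean, sd)
    # normalise each coordinate over its box
    zlo = (lo - prior.beta_prior_mean) / sd
    zhi = (hi - prior.beta_prior_mean) / sd
    log_mass = np.log(stats.norm.cdf(zhi) - stats.norm.cdf(zlo))
    return float(np.sum(lp - log_mass))


def log_prior(state: ParameterState, prior: PriorConfig, bounds: np.ndarray,
              n_obs: int, n_transitions: int) -> float:
    """Joint log prior of a complete parameter state.

    ``bounds`` is the (p, 2) array of beta truncation bounds; ``n_obs``
    and ``n_transitions`` set the sample-size-proportional weights of the
    inverse-gamma variance priors.  The terms add: changing one parameter
    block changes only its own contribution.
    """
    a = np.asarray(state.alpha, dtype=float)
    if a[1] <= 0:
        return -np.inf
    m = np.asarray(prior.alpha_mean, dtype=float)
    v = np.asarray(prior.alpha_var, dtype=float)
    lp = float(np.sum(stats.norm.logpdf(a, m, np.sqrt(v))))
    lp -= float(log_ndtr(m[1] / math.sqrt(v[1])))  # slope truncated at zero

    at, bt = prior.inverse_gamma_hyper(prior.tau2_prior_mean, n_obs)
    asg, bsg = prior.inverse_gamma_hyper(prior.sigma2_prior_mean, n_transitions)
    if state.tau2 <= 0 or state.sigma2 <= 0:
        return -np.inf
    lp += float(stats.invgamma.logpdf(state.tau2, at, scale=bt))
    lp += float(stats.invgamma.logpdf(state.sigma2, asg, scale=bsg))

    lb = _beta_log_prior(state.beta, bounds, prior)
    if not np.isfinite(lb):
        return -np.inf
    lp += lb

    G = np.asarray(state.G, dtype=float)
    q = G.shape[0]
    scale = np.asarray(prior.iw_scale, dtype=float) if prior.iw_scale is not None else np.eye(q)
    df = int(prior.iw_df) if prior.iw_df is not None else q + 1
    try:
        lp += float(stats.invwishart.logpdf(G, df=df, scale=scale))
    except np.linalg.LinAlgError:
        return -np.inf
    gam = np.atleast_2d(state.gamma)
    if q == 1:
        lp += float(np.sum(stats.norm.logpdf(gam[:, 0], 0.0, math.sqrt(G[0, 0]))))
    else:
        lp += float(np.sum(stats.multivariate_normal.logpdf(gam, np.zeros(q), G)))
    return lp
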