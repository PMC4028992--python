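"""Single-site Metropolis kernel for the latent lipid trajectory.

The daily latent update visits the interior days of one individual in a
supplied (permuted) order; endpoints stay fixed.  Because the process
mean is linear in the current lipid mass (the latent-dependent
lipid:lean covariate contributes a slope term), the transition mean is
written mu_t = a_t * L_t + c_t with per-day coefficients precomputed by
the sampler.  The kernel consumes pre-generated proposal increments and
uniforms so that runs are bit-reproducible under one numpy Generator.

Compiled with numba when available; a pure-Python twin with identical
semantics is used otherwise (and exercised in the tests for parity).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@njit(cache=False)
def _log_ndtr(x):
    """log Phi(x), stable far into the lower tail."""
    if x > -1.0:
        return math.log1p(-0.5 * math.erfc(x / _SQRT2))
    if x > -37.0:
        return math.log(0.5 * math.erfc(-x / _SQRT2))
    # asymptotic expansion: Phi(x) ~ phi(x)/(-x) * (1 - 1/x^2)
    return -0.5 * x * x - _LOG_SQRT_2PI - math.log(-x) + math.log1p(-1.0 / (x * x))


@njit(cache=False)
def latent_sweep(L, a, c, obsflag, D, h, R, alpha1, alpha2, tau2, sigma2,
                 prop_sd, normals, uniforms, order):
    """One Metropolis sweep over the interior days of one individual.

    ``L`` is modified in place; returns the number of accepted moves.
    ``order`` indexes the interior days (1..T-1) in update order;
    ``normals``/``uniforms`` supply one variate per visited day.
    """
    acc = 0
    sd = math.sqrt(sigma2)
    for k in range(order.shape[0]):
        t = order[k]
        cur = L[t]
        prop = cur + prop_sd * normals[k]
        if prop < 0.0:
            continue
        dlog = 0.0
        if obsflag[t]:
            mo = alpha1 + alpha2 * cur / R[t]
            mp = alpha1 + alpha2 * prop / R[t]
            w = h[t] / tau2
            dlog += -0.5 * w * ((D[t] - mp) ** 2 - (D[t] - mo) ** 2)
        # transition (t-1) -> t: mean does not involve L_t
        mu_prev = a[t - 1] * L[t - 1] + c[t - 1]
        dlog += -0.5 * ((prop - mu_prev) ** 2 - (cur - mu_prev) ** 2) / sigma2
        # transition t -> t+1: mean (and truncation mass) move with L_t
        if t + 1 <= L.shape[0] - 1:
            mu_old = a[t] * cur + c[t]
            mu_new = a[t] * prop + c[t]
            dlog += -0.5 * ((L[t + 1] - mu_new) ** 2 - (L[t + 1] - mu_old) ** 2) / sigma2
            dlog -= _log_ndtr(mu_new / sd) - _log_ndtr(mu_old / sd)
        if math.log(uniforms[k]) < dlog:
            L[t] = prop
            acc += 1
    return acc


@njit(cache=False)
def latent_chain(L, a, c, obsflag, D, h, R, alpha1, alpha2, tau2, sigma2,
                 prop_sd, normals, uniforms, orders, record_day, out):
    """Many sweeps with all parameters fixed, recording one day's value.

    ``normals``/``uniforms``/``orders`` have shape (n_sweeps, n_interior);
    ``out`` (n_sweeps,) receives L[record_day] after each sweep.  Returns
    total acceptances.
    """
    total = 0
    for s in range(normals.shape[0]):
        total += latent_sweep(L, a, c, obsflag, D, h, R, alpha1, alpha2,
                              tau2, sigma2, prop_sd, normals[s], uniforms[s],
                              orders[s])
        out[s] = L[record_day]
    return total


def latent_sweep_py(L, a, c, obsflag, D, h, R, alpha1, alpha2, tau2, sigma2,
                    prop_sd, normals, uniforms, order):
    """Pure-Python twin of :func:`latent_sweep` (used for parity tests)."""
    from scipy.special import log_ndtr as _lnd

    acc = 0
    sd = math.sqrt(sigma2)
    T = len(L) - 1
    for k in range(len(order)):
        t = int(order[k])
        cur = L[t]
        prop = cur + prop_sd * normals[k]
        if prop < 0.0:
            continue
        dlog = 0.0
        if obsflag[t]:
            mo = alpha1 + alpha2 * cur / R[t]
            mp = alpha1 + alpha2 * prop / R[t]
            w = h[t] / tau2
            dlog += -0.5 * w * ((D[t] - mp) ** 2 - (D[t] - mo) ** 2)
        mu_prev = a[t - 1] * L[t - 1] + c[t - 1]
        dlog += -0.5 * ((prop - mu_prev) ** 2 - (cur - mu_prev) ** 2) / sigma2
        if t + 1 <= T:
            mu_old = a[t] * cur + c[t]
            mu_new = a[t] * prop + c[t]
            dlog += -0.5 * ((L[t + 1] - mu_new) ** 2 - (L[t + 1] - mu_old) ** 2) / sigma2
            dlog -= float(_lnd(mu_new / sd)) - float(_lnd(mu_old / sd))
        if math.log(uniforms[k]) < dlog:
            L[t] = prop
            acc += 1
    return acc
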