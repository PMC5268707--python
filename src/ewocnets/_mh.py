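"""Metropolis-Hastings kernel for the quasi-Bernoulli posterior.

The chain runs on an unconstrained scale: each parameter v_j with prior
box (lo_j, hi_j) is mapped to u_j = logit((v_j - lo_j)/(hi_j - lo_j)),
and the log-Jacobian of the box transform is added to the target so the
chain samples the posterior of v restricted to the box.

The proposal is a mixture: with probability ``w`` an *independence*
draw from the prior (an exact prior sample pushed to the u-scale), and
otherwise a Gaussian random-walk step.  The independence component lets
the chain jump between modes and, in the no-data limit (w = 1), makes
the kept draws exact iid prior samples; the random walk refines locally
once observations accumulate.  The Hastings ratio uses the full mixture
density in both directions.

All randomness (refresh indicators, innovations, prior draws,
acceptance uniforms) is generated by the caller with a seeded numpy
Generator, so draws are bit-reproducible and independent of whether the
numba JIT is available.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=True)(func)

except ImportError:  # pragma: no cover

    def _jit(func):
        return func


_MU_EPS = 1e-12
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _loglik_impl(v, x, cov, s, kind, ltheta, x_min, z_min, z_max):
    """Quasi-Bernoulli log-likelihood at parameter vector v.

    kind: 1 = no covariate (v = gamma, rho1), 2 = binary, 3 = continuous
    (v = gamma, rho1, rho2).
    """
    gamma = v[0]
    denom = gamma - x_min
    if denom < 1e-12:
        return -np.inf
    r1 = v[1]
    if r1 <= 0.0 or r1 >= 1.0:
        return -np.inf
    lr1 = math.log(r1 / (1.0 - r1))
    if kind == 1:
        b1 = (ltheta - lr1) / denom
        b0 = lr1 - b1 * x_min
        delta = 0.0
    else:
        r2 = v[2]
        if r2 <= 0.0 or r2 >= 1.0:
            return -np.inf
        lr2 = math.log(r2 / (1.0 - r2))
        b1 = (ltheta - lr2) / denom
        if kind == 2:
            delta = lr2 - lr1
            b0 = lr1 - b1 * x_min
        else:
            delta = (lr2 - lr1) / (z_max - z_min)
            b0 = lr2 - b1 * x_min - delta * z_max
    ll = 0.0
    for i in range(x.shape[0]):
        eta = b0 + b1 * x[i] + delta * cov[i]
        if eta >= 0.0:
            mu = 1.0 / (1.0 + math.exp(-eta))
        else:
            e = math.exp(eta)
            mu = e / (1.0 + e)
        if mu < _MU_EPS:
            mu = _MU_EPS
        elif mu > 1.0 - _MU_EPS:
            mu = 1.0 - _MU_EPS
        ll += s[i] * math.log(mu) + (1.0 - s[i]) * math.log(1.0 - mu)
    return ll


def _sigmoid(u):
    if u >= 0.0:
        return 1.0 / (1.0 + math.exp(-u))
    e = math.exp(u)
    return e / (1.0 + e)


def _log_jac(u, lo, hi, out_v):
    """Box transform u -> v; returns the log-Jacobian (or -inf if degenerate)."""
    lj = 0.0
    for j in range(u.shape[0]):
        sig = _sigmoid(u[j])
        if sig <= 0.0 or sig >= 1.0:
            return -np.inf
        out_v[j] = lo[j] + (hi[j] - lo[j]) * sig
        lj += math.log(hi[j] - lo[j]) + math.log(sig) + math.log(1.0 - sig)
    return lj


def _log_mix_density(u_from, u_to, lj_to, log_vol, log_w, log_1mw, step):
    """Log density of the mixture proposal moving u_from -> u_to.

    lj_to is the log-Jacobian at u_to; the independence component's
    density on the u-scale is exp(lj_to)/Vol (prior pushforward).
    """
    log_ind = lj_to - log_vol
    if log_1mw == -np.inf:
        return log_ind + log_w  # log_w == 0 here
    lrw = 0.0
    for j in range(u_from.shape[0]):
        d = (u_to[j] - u_from[j]) / step
        lrw += -0.5 * d * d - math.log(step) - _LOG_SQRT_2PI
    if log_w == -np.inf:
        return lrw + log_1mw
    a = log_w + log_ind
    b = log_1mw + lrw
    m = a if a > b else b
    return m + math.log(math.exp(a - m) + math.exp(b - m))


def _chain_impl(
    refresh,
    rw_innov,
    u_prior,
    log_unifs,
    lo,
    hi,
    x,
    cov,
    s,
    kind,
    ltheta,
    x_min,
    z_min,
    z_max,
    n_burn,
    step,
    mix_w,
    enforce_order,
):
    """Run the chain; returns (kept draws of v, accepted count).

    ``refresh[t]`` selects the independence component at step t, in
    which case the proposal is ``u_prior[t]``; otherwise it is
    ``u + rw_innov[t]``.  The chain starts at the prior-box midpoint
    (u = 0).  When ``enforce_order`` is true, states with rho2 > rho1
    (a positive covariate effect on toxicity) are rejected outright.
    """
    n_total, d = rw_innov.shape
    n_keep = n_total - n_burn
    draws = np.empty((n_keep, d))
    log_vol = 0.0
    for j in range(d):
        log_vol += math.log(hi[j] - lo[j])
    log_w = math.log(mix_w) if mix_w > 0.0 else -np.inf
    log_1mw = math.log(1.0 - mix_w) if mix_w < 1.0 else -np.inf

    u = np.zeros(d)
    v = np.empty(d)
    u_prop = np.empty(d)
    v_prop = np.empty(d)

    lj = _log_jac(u, lo, hi, v)
    ll = _loglik(v, x, cov, s, kind, ltheta, x_min, z_min, z_max)
    if enforce_order and d == 3 and v[2] > v[1]:
        ll = -np.inf

    accepted = 0
    for t in range(n_total):
        for j in range(d):
            if refresh[t]:
                u_prop[j] = u_prior[t, j]
            else:
                u_prop[j] = u[j] + rw_innov[t, j]
        lj_prop = _log_jac(u_prop, lo, hi, v_prop)
        if lj_prop > -np.inf:
            ll_prop = _loglik(v_prop, x, cov, s, kind, ltheta, x_min, z_min, z_max)
            if enforce_order and d == 3 and v_prop[2] > v_prop[1]:
                ll_prop = -np.inf
            if ll_prop > -np.inf:
                q_fwd = _log_mix_density(u, u_prop, lj_prop, log_vol, log_w, log_1mw, step)
                q_rev = _log_mix_density(u_prop, u, lj, log_vol, log_w, log_1mw, step)
                log_alpha = (ll_prop + lj_prop) - (ll + lj) + q_rev - q_fwd
                if log_unifs[t] < log_alpha:
                    for j in range(d):
                        u[j] = u_prop[j]
                        v[j] = v_prop[j]
                    ll = ll_prop
                    lj = lj_prop
                    accepted += 1
        if t >= n_burn:
            for j in range(d):
                draws[t - n_burn, j] = v[j]
    return draws, accepted


_loglik = _jit(_loglik_impl)
_sigmoid = _jit(_sigmoid)
_log_jac = _jit(_log_jac)
_log_mix_density = _jit(_log_mix_density)
_run_chain = _jit(_chain_impl)
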