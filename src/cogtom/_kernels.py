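"""Compiled inner loops for belief filtering and the RT likelihood.

The sampler evaluates the filtered LATER likelihood tens of thousands of
times per fit; these numba kernels keep a single evaluation in the tens of
microseconds at the model sizes used (K <= 12, T ~ 1000).  The pure-numpy
implementations in `models` / `later` remain the reference semantics; the
kernels are checked against them in the tests.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG_2PI = math.log(2.0 * math.pi)
P_FLOOR = 1e-6


@njit(cache=True)
def lazy_stationary(pi: np.ndarray) -> np.ndarray:
    """Approximate stationary distribution via the lazy chain (I + pi)/2.

    The lazy chain shares the stationary distribution of ``pi`` but is
    aperiodic, so plain power iteration converges even for cyclic
    transition structures (e.g. the ideal observer's).
    """
    k = pi.shape[0]
    b = np.full(k, 1.0 / k)
    for _ in range(96):
        b = 0.5 * b + 0.5 * (b @ pi)
        b = b / b.sum()
    return b


@njit(cache=True)
def _log_later(rt: float, p: float, theta0: float, mu: float, sigma: float,
               log_trunc: float) -> float:
    if p < P_FLOOR:
        p = P_FLOOR
    elif p > 1.0 - P_FLOOR:
        p = 1.0 - P_FLOOR
    delta = rt - theta0
    if delta <= 0.0:
        return -np.inf
    surprise = -math.log(p)
    r = surprise / delta
    z = (r - mu) / sigma
    return (-0.5 * z * z - math.log(sigma) - 0.5 * LOG_2PI - log_trunc
            + math.log(surprise) - 2.0 * math.log(delta))


@njit(cache=True)
def _truncate_belief(belief: np.ndarray, eps: float) -> None:
    """Zero out the smallest-belief states, keeping at least 1-eps mass.

    In-place; renormalizes.  The retained set is the smallest set of
    largest-weight states whose mass reaches 1-eps.
    """
    k = belief.shape[0]
    order = np.argsort(belief)[::-1]
    cum = 0.0
    cut = k
    for i in range(k):
        cum += belief[order[i]]
        if cum >= 1.0 - eps:
            cut = i + 1
            break
    total = 0.0
    for i in range(cut, k):
        belief[order[i]] = 0.0
    for j in range(k):
        total += belief[j]
    for j in range(k):
        belief[j] /= total


@njit(cache=True)
def filter_rt_loglik(pi: np.ndarray, phi: np.ndarray, obs: np.ndarray,
                     valid: np.ndarray, rt: np.ndarray, theta0: float,
                     mu: float, sigma: float, eps: float,
                     init_belief: np.ndarray) -> float:
    """Log-likelihood of valid-trial RTs under filtered LATER predictions.

    Filtering consumes every stimulus in ``obs`` (0-based alphabet); only
    trials flagged in ``valid`` contribute RT terms.  ``eps`` > 0 applies
    slice truncation of the belief to its 1-eps support after every
    update.  Returns -inf for impossible observations or unsupported RTs.
    """
    t_n = obs.shape[0]
    belief = init_belief.copy()
    log_trunc = math.log(0.5 * (1.0 + math.erf((mu / sigma) / math.sqrt(2.0))))
    ll = 0.0
    for t in range(t_n):
        y = obs[t]
        prop = belief @ pi
        if valid[t]:
            p_n = 0.0
            for k in range(prop.shape[0]):
                p_n += prop[k] * phi[k, y]
            term = _log_later(rt[t], p_n, theta0, mu, sigma, log_trunc)
            if not np.isfinite(term):
                return -np.inf
            ll += term
        new = prop * phi[:, y]
        total = new.sum()
        if total <= 0.0:
            return -np.inf
        belief = new / total
        if eps > 0.0:
            _truncate_belief(belief, eps)
    return ll


@njit(cache=True)
def filter_predictions(pi: np.ndarray, phi: np.ndarray, obs: np.ndarray,
                       init_belief: np.ndarray) -> np.ndarray:
    """(T, 4) next-stimulus predictions, row t made before observing obs[t]."""
    t_n = obs.shape[0]
    out = np.empty((t_n, 4))
    belief = init_belief.copy()
    for t in range(t_n):
        prop = belief @ pi
        pred = prop @ phi
        out[t] = pred / pred.sum()
        new = prop * phi[:, obs[t]]
        total = new.sum()
        if total <= 0.0:
            raise ValueError("observation impossible under every reachable state")
        belief = new / total
    return out


@njit(cache=True)
def filter_occupancy(pi: np.ndarray, phi: np.ndarray, obs: np.ndarray,
                     init_belief: np.ndarray) -> np.ndarray:
    """Mean filtered belief mass per state over the sequence."""
    t_n = obs.shape[0]
    belief = init_belief.copy()
    occ = np.zeros(pi.shape[0])
    for t in range(t_n):
        prop = belief @ pi
        new = prop * phi[:, obs[t]]
        total = new.sum()
        if total <= 0.0:
            raise ValueError("observation impossible under every reachable state")
        belief = new / total
        occ += belief
    return occ / t_n


@njit(cache=True)
def later_loglik(ps: np.ndarray, rts: np.ndarray, theta0: float, mu: float,
                 sigma: float) -> float:
    """Sum of LATER log-densities for fixed per-trial probabilities."""
    log_trunc = math.log(0.5 * (1.0 + math.erf((mu / sigma) / math.sqrt(2.0))))
    ll = 0.0
    for i in range(ps.shape[0]):
        term = _log_later(rts[i], ps[i], theta0, mu, sigma, log_trunc)
        if not np.isfinite(term):
            return -np.inf
        ll += term
    return ll
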