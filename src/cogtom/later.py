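"""LATER response-time model.

Response times are modelled as an offset plus the time a linearly rising
decision signal needs to cover a distance proportional to the surprise of
the upcoming stimulus:

    RT = theta0 + (-log p) / r,        r ~ Normal(mu, sigma) truncated to r > 0

where ``p`` is the subjective probability of the stimulus that actually
appears.  The rate ``r`` varies from trial to trial, making RT
reciprocal-normal; truncating ``r`` at zero keeps every response time
above the offset.  All times are in seconds internally (file formats carry
milliseconds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

#: subjective probabilities are floored here before taking logs so that a
#: hypothesis assigning probability ~1 still yields a finite, non-degenerate
#: RT likelihood
P_FLOOR = 1e-6


@dataclass
class LaterParams:
    """theta0: offset (s); mu, sigma: mean and sd of the rate r (1/s)."""

    theta0: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (np.isfinite([self.theta0, self.mu, self.sigma]).all()):
            raise ValueError("LATER parameters must be finite")
        if self.theta0 < 0 or self.mu <= 0 or self.sigma <= 0:
            raise ValueError(
                f"need theta0 >= 0, mu > 0, sigma > 0; got {self}"
            )


def _check_p(p: float) -> float:
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    return p


def rt_density(rt, p: float, params: LaterParams):
    """Density of RT at subjective probability ``p``.

    Change of variables from the truncated normal rate:
    f(rt) = N(r; mu, sigma) / Phi(mu/sigma) * (-log p) / (rt - theta0)^2
    with r = (-log p)/(rt - theta0); zero for rt <= theta0.  For p = 1 the
    distribution is a point mass at theta0 and has no density.
    """
    _check_p(p)
    if p == 1.0:
        raise ValueError(
            "p = 1 gives a degenerate RT distribution (point mass at theta0); "
            "handle it as the point-mass case (see sample_rt / map_rt)"
        )
    rt = np.asarray(rt, dtype=float)
    d = np.zeros_like(rt)
    surprise = -np.log(p)
    trunc_z = stats.norm.cdf(params.mu / params.sigma)
    ok = rt > params.theta0
    delta = rt[ok] - params.theta0
    r = surprise / delta
    d[ok] = stats.norm.pdf(r, params.mu, params.sigma) / trunc_z * surprise / delta**2
    return d if d.ndim else float(d)


def sample_rt(
    p, params: LaterParams, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw RTs at subjective probabilities ``p`` (scalar or array).

    Rates come from Normal(mu, sigma) truncated to r > 0; p = 1 entries
    return theta0 exactly (zero surprise, nothing to accumulate).
    """
    rng = np.random.default_rng(seed)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("all p must be in (0, 1]")
    a = -params.mu / params.sigma  # truncation at r = 0 in standard units
    r = stats.truncnorm.rvs(
        a, np.inf, loc=params.mu, scale=params.sigma, size=p.shape, random_state=rng
    )
    rt = params.theta0 + (-np.log(p)) / r
    rt[p == 1.0] = params.theta0
    return rt if rt.size > 1 else float(rt[0])


def map_rt(p, params: LaterParams, exact_mode: bool = False):
    """Point RT prediction at subjective probability ``p``.

    Default is the plug-in prediction theta0 + (-log p)/mu (the RT at the
    mean rate); ``exact_mode`` instead locates the mode of ``rt_density``
    numerically.  Probabilities are floored at P_FLOOR so predictions stay
    finite.
    """
    p = np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0)
    if (p <= 0).any():
        raise ValueError("p must be positive")
    plug_in = params.theta0 + (-np.log(p)) / params.mu
    if not exact_mode:
        return plug_in if plug_in.ndim else float(plug_in)
    scalar = plug_in.ndim == 0
    p_flat = np.atleast_1d(p)
    out = np.empty_like(p_flat)
    for i, pi in enumerate(p_flat):
        if pi >= 1.0:
            out[i] = params.theta0
            continue
        guess = params.theta0 + (-np.log(pi)) / params.mu
        res = optimize.minimize_scalar(
            lambda rt: -rt_density(rt, pi, params),
            bracket=(params.theta0 + 0.25 * (guess - params.theta0), guess),
        )
        out[i] = res.x
    return float(out[0]) if scalar else out.reshape(np.shape(p))


def residual_qq(
    rts: np.ndarray, ps: np.ndarray, params: LaterParams
) -> tuple[np.ndarray, np.ndarray]:
    """QQ pairs of the z-scored recovered rates against the standard normal.

    Inverts the model per trial, r = (-log p)/(rt - theta0), z-scores the
    recovered rates and pairs their order statistics with standard-normal
    quantiles.  Under the model the points fall on the identity line;
    curvature flags violations such as bimodal residuals.
    """
    rts = np.asarray(rts, dtype=float)
    ps = np.clip(np.asarray(ps, dtype=float), P_FLOOR, 1.0 - P_FLOOR)
    if rts.shape != ps.shape:
        raise ValueError("rts and ps must have equal length")
    bad = np.flatnonzero(rts <= params.theta0)
    if bad.size:
        raise ValueError(f"rt <= theta0 at trials (0-based): {bad.tolist()[:10]}")
    r = (-np.log(ps)) / (rts - params.theta0)
    if np.std(r) <= 1e-10 * max(1.0, abs(float(np.mean(r)))):
        raise ValueError("recovered rates have zero variance; QQ undefined")
    z = np.sort((r - r.mean()) / r.std())
    n = len(z)
    theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theoretical, z
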