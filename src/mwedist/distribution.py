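"""Closed-form functions of the Modified Weibull Extension distribution (MWED).

The MWED is a three-parameter lifetime model with scale ``theta`` and shape
parameters ``sigma`` and ``mu``.  Writing ``z = (x/theta)**sigma``, its hazard
rate is ``sigma*mu*(x/theta)**(sigma-1) * exp(z)`` and its cumulative hazard is
``mu*theta*(exp(z) - 1)``, which gives the closed forms

    f(x) = sigma*mu*(x/theta)**(sigma-1) * exp(z + mu*theta*(1 - exp(z)))
    F(x) = 1 - exp(mu*theta*(1 - exp(z)))
    R(x) = exp(mu*theta*(1 - exp(z)))

The hazard is increasing when ``sigma >= 1`` and bathtub-shaped (decreasing,
then increasing) when ``sigma < 1``, which is why the model is attractive for
survival times of patients.  The Weibull distribution is a limiting case.

All functions accept scalars or numpy arrays for ``x`` and are numerically
guarded: the inner exponent is evaluated with ``expm1`` so that the survival
function underflows cleanly to 0 (and the CDF saturates at 1) instead of
overflowing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Params",
    "pdf",
    "logpdf",
    "cdf",
    "reliability",
    "log_reliability",
    "hazard",
    "quantile",
    "sample",
]


@dataclass(frozen=True)
class Params:
    """MWED parameter triple; all three must be strictly positive.

    Parameters
    ----------
    theta : float
        Scale, in the same units as the time variable.
    sigma : float
        Shape; controls the hazard regime (>=1 increasing, <1 bathtub).
    mu : float
        Shape; scales the hazard level.
    """

    theta: float
    sigma: float
    mu: float

    def __post_init__(self) -> None:
        for name in ("theta", "sigma", "mu"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(f"{name} must be a finite positive real, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.sigma, self.mu], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Params":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))


def _check_x(x, allow_zero: bool = True) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo = 0.0 if allow_zero else np.nextafter(0.0, 1.0)
    if np.any(x < lo) or (not allow_zero and np.any(x <= 0.0)):
        raise ValueError("x must be nonnegative" if allow_zero else "x must be strictly positive")
    return x


def _z(x: np.ndarray, p: Params) -> np.ndarray:
    return (x / p.theta) ** p.sigma


def logpdf(x, p: Params):
    """Log-density; -inf where the density vanishes (including x=0 for sigma>1)."""
    x = _check_x(x)
    scalar = np.ndim(x) == 0
    x = np.atleast_1d(x)
    out = np.full(x.shape, -np.inf)
    pos = x > 0.0
    with np.errstate(over="ignore"):
        z = _z(x[pos], p)
        out[pos] = (
            np.log(p.sigma)
            + np.log(p.mu)
            + (p.sigma - 1.0) * np.log(x[pos] / p.theta)
            + z
            - p.mu * p.theta * np.expm1(z)
        )
    if np.any(~pos):
        # continuity at the origin: 0 for sigma>1, sigma*mu for sigma=1,
        # +inf for sigma<1 (density blows up like x**(sigma-1))
        at0 = -np.inf if p.sigma > 1.0 else (np.log(p.sigma * p.mu) if p.sigma == 1.0 else np.inf)
        out[~pos] = at0
    return float(out[0]) if scalar else out


def pdf(x, p: Params):
    """Density of the MWED; returns +inf at x=0 when sigma < 1 (integrable pole)."""
    out = np.exp(logpdf(x, p))
    return out


def log_reliability(x, p: Params):
    """log R(x) = mu*theta*(1 - exp((x/theta)**sigma)), computed via expm1."""
    x = _check_x(x)
    with np.errstate(over="ignore"):
        return -p.mu * p.theta * np.expm1(_z(x, p))


def reliability(x, p: Params):
    """Survival function R(x) = 1 - F(x); R(0) = 1, nonincreasing."""
    return np.exp(log_reliability(x, p))


def cdf(x, p: Params):
    """Distribution function F(x) = 1 - exp(mu*theta*(1 - exp((x/theta)**sigma)))."""
    return -np.expm1(log_reliability(x, p))


def hazard(x, p: Params):
    """Failure-rate function, the ratio pdf/reliability in closed form.

    Equals ``sigma*mu*(x/theta)**(sigma-1)*exp((x/theta)**sigma)``; defined for
    x > 0 only (at x=0 it vanishes for sigma>1 and diverges for sigma<1).
    """
    x = _check_x(x, allow_zero=False)
    with np.errstate(over="ignore"):
        z = _z(x, p)
        return p.sigma * p.mu * (x / p.theta) ** (p.sigma - 1.0) * np.exp(z)


def quantile(u, p: Params):
    """Inverse CDF: x = theta * [ln(1 - ln(1-u)/(mu*theta))]**(1/sigma).

    Valid for u in the open interval (0, 1); strictly increasing in u and the
    exact inverse of :func:`cdf` (round-trip error below 1e-10).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    # -log1p(-u) = -ln(1-u) >= 0, so the inner log1p argument is >= 0
    inner = np.log1p(-np.log1p(-u) / (p.mu * p.theta))
    return p.theta * inner ** (1.0 / p.sigma)


def sample(n: int, p: Params, seed) -> np.ndarray:
    """Draw ``n`` variates by inverse-transform sampling of uniform draws.

    ``seed`` may be an int or a ``numpy.random.Generator``; identical integer
    seeds give identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    # uniform() can emit exactly 0.0; nudge into the open interval
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    return quantile(u, p)
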