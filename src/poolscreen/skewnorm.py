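"""Skew-normal distribution in the Fernandez–Steel (inverse-scale-factor)
parameterization, standardized so that ``location`` and ``scale`` are the
mean and standard deviation regardless of the skew.

A standard normal Z is skewed by the parameter xi > 0 by rescaling its two
halves: the "raw" density is

    f(z; xi) = 2/(xi + 1/xi) * [ phi(z/xi) * 1{z >= 0} + phi(z*xi) * 1{z < 0} ]

with xi = 1 symmetric, xi > 1 right-skewed, xi < 1 left-skewed. The raw
family has mean m(xi) = M1*(xi - 1/xi) (M1 = sqrt(2/pi)) and variance
s(xi)^2 = (1 - M1^2)*(xi^2 + 1/xi^2) + 2*M1^2 - 1, both depending on xi;
fitting location jointly with skew on the raw family is badly identified
because a shifted, strongly skewed member can imitate a centred mild one
over the central quantiles. The standardized family used here,

    X = location + scale * (Z_raw - m(xi)) / s(xi),

removes that ridge: location is E[X] and scale is SD[X] for every xi, and
xi = 1 reduces exactly to N(location, scale^2). Both cdf and quantile
function are closed-form through the normal cdf/quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidParameterError

__all__ = ["SkewNormalParams", "pdf", "cdf", "ppf", "rvs"]

_M1 = np.sqrt(2.0 / np.pi)


@dataclass(frozen=True)
class SkewNormalParams:
    """Location (mean), scale (sd) and skew of one null; skew = 1 is symmetric."""

    location: float
    scale: float
    skew: float
    converged: bool = True  # False when the symmetric fallback was used
    n: int = 0  # number of LFCs the fit was based on

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise InvalidParameterError("scale must be > 0")
        if self.skew <= 0:
            raise InvalidParameterError("skew must be > 0")


def _unpack(params) -> tuple[float, float, float]:
    if isinstance(params, SkewNormalParams):
        return params.location, params.scale, params.skew
    location, scale, skew = params
    if scale <= 0 or skew <= 0:
        raise InvalidParameterError("scale and skew must be > 0")
    return location, scale, skew


def _moments(skew: float) -> tuple[float, float]:
    """Mean and sd of the raw (unstandardized) FS family."""
    m = _M1 * (skew - 1.0 / skew)
    s2 = (1.0 - _M1**2) * (skew**2 + skew**-2) + 2.0 * _M1**2 - 1.0
    return m, np.sqrt(s2)


def pdf(x, params):
    location, scale, skew = _unpack(params)
    m, s = _moments(skew)
    z = m + s * (np.asarray(x, dtype=float) - location) / scale
    norm_const = 2.0 / (skew + 1.0 / skew)
    raw = norm_const * np.where(
        z >= 0, stats.norm.pdf(z / skew), stats.norm.pdf(z * skew)
    )
    out = raw * s / scale
    return float(out) if out.ndim == 0 else out


def cdf(x, params):
    """Cumulative distribution function; exact via the normal cdf."""
    location, scale, skew = _unpack(params)
    m, s = _moments(skew)
    z = m + s * (np.asarray(x, dtype=float) - location) / scale
    s2 = skew * skew
    left = 2.0 / (s2 + 1.0) * stats.norm.cdf(z * skew)
    right = 1.0 / (s2 + 1.0) + 2.0 * s2 / (s2 + 1.0) * (
        stats.norm.cdf(z / skew) - 0.5
    )
    out = np.where(z < 0, left, right)
    return float(out) if out.ndim == 0 else out


def ppf(q, params):
    """Quantile function (inverse of :func:`cdf`)."""
    location, scale, skew = _unpack(params)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(q >= 1):
        raise InvalidParameterError("quantile levels must lie in (0, 1)")
    m, s = _moments(skew)
    s2 = skew * skew
    p_zero = 1.0 / (s2 + 1.0)  # cdf mass left of the junction point
    with np.errstate(invalid="ignore"):
        z_left = stats.norm.ppf(q * (s2 + 1.0) / 2.0) / skew
        z_right = skew * stats.norm.ppf((q - p_zero) * (s2 + 1.0) / (2.0 * s2) + 0.5)
    z = np.where(q < p_zero, z_left, z_right)
    out = location + scale * (z - m) / s
    return float(out) if out.ndim == 0 else out


def rvs(params, size, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Random sample via inverse-cdf of uniforms."""
    rng = np.random.default_rng(rng)
    u = rng.uniform(size=size)
    u = np.clip(u, 1e-300, 1 - 1e-16)  # exact 0/1 would be out of domain
    return np.asarray(ppf(u, params))
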