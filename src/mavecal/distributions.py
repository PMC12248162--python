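"""Skew-normal distribution primitives.

Assay score distributions are modeled with the three-parameter skew-normal
family SN(mu, omega, lambda) with density

    f(x) = (2 / omega) * phi((x - mu) / omega) * Phi(lambda * (x - mu) / omega),

where ``phi`` and ``Phi`` are the standard normal pdf and cdf.  The EM
updates work in the alternate parameterization (mu, Delta, Gamma) that comes
from the constructive representation

    X = mu + Delta * T + sqrt(Gamma) * U,

with ``T`` standard normal truncated below zero (half-normal) and ``U``
standard normal.  The two parameterizations are related by

    Delta = omega * lambda / sqrt(1 + lambda**2),
    Gamma = omega**2 - Delta**2,

so that ``lambda = Delta / sqrt(Gamma)`` and ``omega**2 = Delta**2 + Gamma``.

Density and CDF evaluations are delegated to :mod:`scipy.stats.skewnorm`;
a fast log-density in :mod:`scipy.special` terms is provided for the EM hot
loop.  Sampling uses the constructive representation with an explicit seed
contract (same seed, same bytes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "SkewNormalParams",
    "AlternateParams",
    "sn_pdf",
    "sn_logpdf",
    "sn_cdf",
    "sn_sample",
    "sn_mean",
    "sn_var",
    "canonical_to_alternate",
    "alternate_to_canonical",
]

_LOG2 = math.log(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SkewNormalParams:
    """Canonical skew-normal parameters (location, scale, skew)."""

    location: float
    scale: float
    skew: float

    def __post_init__(self) -> None:
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError(f"scale must be a positive finite real, got {self.scale}")
        if not (math.isfinite(self.location) and math.isfinite(self.skew)):
            raise ValueError("location and skew must be finite")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.location, self.scale, self.skew)


@dataclass(frozen=True)
class AlternateParams:
    """Alternate parameterization (location, Delta, Gamma) used by the M-step."""

    location: float
    delta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.gamma >= 0 and math.isfinite(self.gamma)):
            raise ValueError(f"gamma must be a nonnegative finite real, got {self.gamma}")
        if not (math.isfinite(self.location) and math.isfinite(self.delta)):
            raise ValueError("location and delta must be finite")


def canonical_to_alternate(params: SkewNormalParams) -> AlternateParams:
    """Map (mu, omega, lambda) to (mu, Delta, Gamma)."""
    lam = params.skew
    delta_unit = lam / math.sqrt(1.0 + lam * lam)
    delta = params.scale * delta_unit
    gamma = params.scale**2 * (1.0 - delta_unit**2)
    return AlternateParams(location=params.location, delta=delta, gamma=gamma)


def alternate_to_canonical(params: AlternateParams) -> SkewNormalParams:
    """Map (mu, Delta, Gamma) back to (mu, omega, lambda)."""
    if params.gamma <= 0:
        raise ValueError("gamma must be strictly positive to recover a finite skew")
    omega = math.sqrt(params.delta**2 + params.gamma)
    lam = params.delta / math.sqrt(params.gamma)
    return SkewNormalParams(location=params.location, scale=omega, skew=lam)


def sn_pdf(x, params: SkewNormalParams):
    """Skew-normal density, vectorized over ``x``."""
    return stats.skewnorm.pdf(x, params.skew, loc=params.location, scale=params.scale)


def sn_logpdf(x, location: float, scale: float, skew: float):
    """Log-density via scipy.special, bypassing distribution machinery.

    Numerically equivalent to ``skewnorm.logpdf`` but cheap enough for the
    EM inner loop; stable for large ``|skew * z|`` through ``log_ndtr``.
    """
    z = (np.asarray(x, dtype=float) - location) / scale
    return (
        _LOG2
        - math.log(scale)
        - 0.5 * z * z
        - _LOG_SQRT_2PI
        + special.log_ndtr(skew * z)
    )


def sn_cdf(x, params: SkewNormalParams):
    """Skew-normal CDF (Owen's T based, via scipy)."""
    return stats.skewnorm.cdf(x, params.skew, loc=params.location, scale=params.scale)


def sn_sample(params: SkewNormalParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` variates using the half-normal construction.

    ``seed`` may be an int or a ``numpy.random.Generator``.  The same seed
    yields byte-identical output.
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    alt = canonical_to_alternate(params)
    t = np.abs(rng.standard_normal(n))  # standard normal truncated below 0
    u = rng.standard_normal(n)
    return params.location + alt.delta * t + math.sqrt(alt.gamma) * u


def sn_mean(params: SkewNormalParams) -> float:
    """Closed-form mean: mu + omega * delta * sqrt(2/pi)."""
    delta_unit = params.skew / math.sqrt(1.0 + params.skew**2)
    return params.location + params.scale * delta_unit * math.sqrt(2.0 / math.pi)


def sn_var(params: SkewNormalParams) -> float:
    """Closed-form variance: omega^2 * (1 - 2*delta^2/pi)."""
    delta_unit = params.skew / math.sqrt(1.0 + params.skew**2)
    return params.scale**2 * (1.0 - 2.0 * delta_unit**2 / math.pi)
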