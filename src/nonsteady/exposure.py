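"""Zero-inflated gamma model for daily toxicant intakes.

Daily intake on any given day is zero with probability ``1 - omega``
(no contact with the exposure source that day) and otherwise follows a
gamma distribution describing the magnitude of exposure on exposure
days.  The gamma component is parameterized by the *log* of its mean
(``beta``) and the *log* of its variance (``alpha``): both are
unrestricted real numbers, which keeps downstream estimation free of
boundary constraints, and the mean of the biomarker model depends on
``beta`` alone once the exposure frequency ``omega`` is known (e.g.
from a food-frequency questionnaire).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ZIGExposureParams",
    "to_shape_rate",
    "from_shape_rate",
    "unconditional_moments",
    "sample_daily_exposures",
]


@dataclass(frozen=True)
class ZIGExposureParams:
    """Parameters of the zero-inflated gamma daily-exposure distribution.

    Attributes
    ----------
    omega : float
        Exposure frequency (day**-1): probability of a non-zero exposure
        on any given day.  ``omega = 0`` is permitted only as a degenerate
        "never exposed" marker; estimation requires ``omega > 0``.
    alpha : float
        Log of the conditional (exposure-day) variance of exposure
        magnitude, log(ug**2 d**-2).  Unrestricted real.
    beta : float
        Log of the conditional mean exposure magnitude, log(ug d**-1).
        Unrestricted real.
    """

    omega: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError("alpha and beta must be finite reals")

    @property
    def mu(self) -> float:
        """Conditional mean exposure magnitude e**beta (ug d**-1)."""
        return math.exp(self.beta)

    @property
    def sigma_g2(self) -> float:
        """Conditional exposure-magnitude variance e**alpha (ug**2 d**-2)."""
        return math.exp(self.alpha)


def to_shape_rate(p: ZIGExposureParams) -> tuple[float, float]:
    """Shape/rate parameters of the gamma component.

    The gamma with mean ``m = e**beta`` and variance ``s2 = e**alpha``
    has shape ``m**2/s2 = exp(2*beta - alpha)`` and rate
    ``m/s2 = exp(beta - alpha)``.
    """
    shape = math.exp(2.0 * p.beta - p.alpha)
    rate = math.exp(p.beta - p.alpha)
    return shape, rate


def from_shape_rate(omega: float, shape: float, rate: float) -> ZIGExposureParams:
    """Inverse of :func:`to_shape_rate` (round-trips to floating tolerance)."""
    if shape <= 0 or rate <= 0:
        raise ValueError("shape and rate must be positive")
    beta = math.log(shape) - math.log(rate)
    alpha = math.log(shape) - 2.0 * math.log(rate)
    return ZIGExposureParams(omega=omega, alpha=alpha, beta=beta)


def unconditional_moments(p: ZIGExposureParams) -> tuple[float, float]:
    """Mean and variance of the daily intake including zero days.

    By total expectation/variance over the exposure indicator,

    ``E I   = omega * e**beta``
    ``Var I = omega * e**alpha + omega * (1 - omega) * e**(2*beta)``
    """
    m = math.exp(p.beta)
    mean = p.omega * m
    var = p.omega * math.exp(p.alpha) + p.omega * (1.0 - p.omega) * m * m
    return mean, var


def sample_daily_exposures(
    p: ZIGExposureParams,
    t: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """Draw ``t`` i.i.d. daily intakes (ug d**-1).

    Each day is independently zero with probability ``1 - omega`` and
    otherwise a gamma(shape, rate) draw.  Reproducible under a fixed
    seed; a :class:`numpy.random.Generator` may be passed directly when
    the caller manages its own stream.
    """
    if t < 1:
        raise ValueError(f"number of days t must be >= 1, got {t}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.zeros(t, dtype=float)
    if p.omega == 0.0:
        return out
    mask = rng.random(t) < p.omega
    n_on = int(mask.sum())
    if n_on:
        shape, rate = to_shape_rate(p)
        out[mask] = rng.gamma(shape, 1.0 / rate, size=n_on)
    return out
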