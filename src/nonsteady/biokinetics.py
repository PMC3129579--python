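"""Discrete-time exposure weights for a one-compartment biokinetic model.

A blood biomarker measured on day ``t`` is a weighted sum of all prior
daily intakes.  Under first-order elimination the day-``j`` intake
contributes with weight ``(f/v) * exp(-k*(t - j))``: the intake is
diluted into the blood volume ``v`` after a fraction ``f`` is absorbed,
then decays exponentially at rate ``k``.  Hair-segment weights average
the blood weight over the segment's growth window and scale by the
hair-to-blood partition ratio ``h``.

The geometric-series sums S1 and S2 of the (squared) decay factors give
closed forms for the model-implied biomarker mean and variance without
summing over the full exposure history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BiokineticParams",
    "MERCURY_DEFAULTS",
    "blood_weight",
    "weight_sums",
    "hair_segment_weight",
    "steady_state_ratio",
]


@dataclass(frozen=True)
class BiokineticParams:
    """Per-individual constants of the one-compartment model.

    Attributes
    ----------
    f : float
        Fraction of the ingested dose reaching the blood after
        absorption and equilibration (dimensionless, 0 < f <= 1).
    v : float
        Blood volume (L).
    k : float
        First-order elimination rate coefficient (day**-1);
        half-life = ln(2)/k.
    h : float or None
        Hair-to-blood equilibrium partition ratio (dimensionless),
        required only for hair-segment weights.
    """

    f: float = 0.0475
    v: float = 5.0
    k: float = 0.014
    h: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.f <= 1.0:
            raise ValueError(f"absorbed fraction f must lie in (0, 1], got {self.f}")
        if self.v <= 0:
            raise ValueError(f"blood volume v must be positive, got {self.v}")
        if self.k <= 0:
            raise ValueError(f"elimination rate k must be positive, got {self.k}")
        if self.h is not None and self.h <= 0:
            raise ValueError(f"hair ratio h must be positive, got {self.h}")

    @property
    def half_life(self) -> float:
        """Elimination half-life ln(2)/k (days)."""
        return math.log(2.0) / self.k


#: Methylmercury reference values: absorbed fraction 0.0475, 5 L blood,
#: elimination rate 0.014/day (half-life ~50 days).
MERCURY_DEFAULTS = BiokineticParams()


def blood_weight(bk: BiokineticParams, j, t) -> np.ndarray | float:
    """Influence (L**-1) of the day-``j`` intake on the day-``t`` blood level.

    ``(f/v) * exp(-k*(t - j))`` for ``1 <= j <= t``; zero for ``j > t``
    (a measurement cannot anticipate future intakes) and for ``j < 1``
    (outside the modeled history).
    """
    j = np.asarray(j, dtype=float)
    t = np.asarray(t, dtype=float)
    w = (bk.f / bk.v) * np.exp(-bk.k * (t - j))
    w = np.where((j > t) | (j < 1), 0.0, w)
    return w if w.ndim else float(w)


def weight_sums(bk: BiokineticParams, t: int) -> tuple[float, float]:
    """Geometric sums S1 = sum_j exp(-k(t-j)) and S2 = same at rate 2k.

    ``S1 = (1 - e**(-k t)) / (1 - e**(-k))`` enters the biomarker mean;
    ``S2`` (with ``2k``) enters the variance.  ``expm1`` keeps both
    accurate for small ``k``.
    """
    if t < 1:
        raise ValueError(f"horizon t must be >= 1, got {t}")
    s1 = math.expm1(-bk.k * t) / math.expm1(-bk.k)
    s2 = math.expm1(-2.0 * bk.k * t) / math.expm1(-2.0 * bk.k)
    return s1, s2


def hair_segment_weight(bk: BiokineticParams, j, t1: int, t2: int) -> np.ndarray | float:
    """Influence of the day-``j`` intake on a hair segment grown over days
    ``t1..t2`` (inclusive).

    The segment concentration is modeled as the hair ratio ``h`` times
    the day-averaged blood concentration over the growth window, so the
    weight is ``h * (f/v)`` times the mean of ``exp(-k*(tau - j))`` over
    ``tau = max(j, t1) .. t2``, and zero for ``j > t2``.  The inner sum
    is evaluated in closed form as a geometric series.
    """
    if bk.h is None:
        raise ValueError("hair_segment_weight requires BiokineticParams.h")
    if t1 > t2:
        raise ValueError(f"segment requires t1 <= t2, got t1={t1}, t2={t2}")
    j = np.asarray(j, dtype=float)
    a = np.maximum(j, float(t1))  # first growth day influenced by intake j
    n_days = t2 - t1 + 1
    ek = math.exp(-bk.k)
    # sum_{tau=a..t2} e^{-k(tau-j)} = e^{-k(a-j)} (1 - e^{-k(t2-a+1)})/(1-e^{-k})
    geo = np.exp(-bk.k * (a - j)) * -np.expm1(-bk.k * (t2 - a + 1)) / (1.0 - ek)
    w = bk.h * (bk.f / bk.v) * geo / n_days
    w = np.where((j > t2) | (j < 1), 0.0, w)
    return w if w.ndim else float(w)


def steady_state_ratio(bk: BiokineticParams) -> float:
    """Steady-state intake-to-blood ratio b = k*v/f (ug d**-1 per ug L**-1).

    Under a constant intake rate I the blood concentration settles at
    ``I*f/(v*k)``, so multiplying a steady-state concentration by ``b``
    recovers the intake rate.
    """
    return bk.k * bk.v / bk.f
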