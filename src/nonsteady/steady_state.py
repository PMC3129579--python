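"""Steady-state comparison estimators and their closed-form error.

The conventional approach multiplies an individual's biomarker
concentration by the steady-state ratio ``b = k*v/f`` to obtain an
intake-rate estimate.  When daily intakes are intermittent
(zero-inflated), ``b*y`` estimates the *unconditional* mean intake
``omega*mu`` rather than the exposure-day mean ``mu``, so it is biased
by roughly ``mu*(omega - 1)``; dividing by the known exposure frequency
(``b*y/omega``) removes that bias.  Both the bias and the sampling
standard error of the naive estimate have closed forms under the
discrete-time convolution model, evaluated here exactly at a finite
exposure history ``t``.
"""

from __future__ import annotations

import math

import numpy as np

from .biokinetics import BiokineticParams, steady_state_ratio, weight_sums
from .exposure import ZIGExposureParams, unconditional_moments

__all__ = ["naive_estimate", "modified_estimate", "closed_form_bias_and_se"]


def naive_estimate(y, bk: BiokineticParams):
    """Steady-state intake estimate b*y (ug d**-1)."""
    b = steady_state_ratio(bk)
    out = b * np.asarray(y, dtype=float)
    return out if out.ndim else float(out)


def modified_estimate(y, bk: BiokineticParams, omega: float):
    """Frequency-corrected steady-state estimate b*y/omega.

    Targets the exposure-day mean ``mu``; nearly unbiased for long
    exposure histories (its expectation is ``mu`` times the discrete
    steady-state factor ``b*(f/v)*S1(t)``, which is 1 + O(k) and
    approaches ``k/(1 - e**-k)`` as t grows).
    """
    if np.any(np.asarray(omega) <= 0):
        raise ValueError("modified_estimate requires omega > 0")
    out = naive_estimate(y, bk) / np.asarray(omega, dtype=float)
    return out if out.ndim else float(out)


def closed_form_bias_and_se(
    bk: BiokineticParams,
    p: ZIGExposureParams,
    sigma_eps2: float,
    t: int,
) -> tuple[float, float]:
    """Per-individual bias and standard error of the naive estimate b*y.

    With ``E y = omega * e**beta * (f/v) * S1(t)`` and
    ``Var y = (f/v)**2 * S2(t) * VarI + sigma_eps2``,

    ``bias = b * E y - mu  ~=  mu * (omega - 1)``
    ``se   = b * sqrt((f/v)**2 * S2(t) * VarI + sigma_eps2)``

    where VarI is the unconditional daily-intake variance.  The bias is
    returned exactly for the finite history ``t`` (the familiar
    ``mu*(omega - 1)`` is its long-history continuous-time limit, the
    two differing only by the discretization factor ``k/(1 - e**-k)``).
    """
    if sigma_eps2 < 0:
        raise ValueError("sigma_eps2 must be non-negative")
    s1, s2 = weight_sums(bk, t)
    b = steady_state_ratio(bk)
    fv = bk.f / bk.v
    mu = math.exp(p.beta)
    _, var_i = unconditional_moments(p)
    bias = b * p.omega * mu * fv * s1 - mu
    se = b * math.sqrt(fv**2 * s2 * var_i + sigma_eps2)
    return bias, se
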