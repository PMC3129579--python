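"""Shared fixtures and independent brute-force oracles.

The oracles recompute biomarker moments by direct daily convolution --
summing explicit per-day weights -- never through the closed-form
geometric sums used by the package.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from nonsteady import BiokineticParams, BiomarkerDataset, ZIGExposureParams

MU = 10.0
SIGMA_G2 = 5.0
SIGMA_EPS2 = 0.03**2
T_STUDY = 1000


@pytest.fixture(scope="session")
def mercury() -> BiokineticParams:
    return BiokineticParams(f=0.0475, v=5.0, k=0.014)


@pytest.fixture(scope="session")
def study_params() -> ZIGExposureParams:
    """The reference study condition: omega = 0.5, mu = 10, sigma_g2 = 5."""
    return ZIGExposureParams(omega=0.5, alpha=math.log(SIGMA_G2), beta=math.log(MU))


def brute_weights(bk: BiokineticParams, t: int) -> np.ndarray:
    """Per-day blood weights (f/v) e^{-k (t-j)}, j = 1..t, by direct evaluation."""
    j = np.arange(1, t + 1, dtype=float)
    return (bk.f / bk.v) * np.exp(-bk.k * (t - j))


def brute_mean_var(
    omega: float,
    t: int,
    bk: BiokineticParams,
    alpha: float,
    beta: float,
    sigma_eps2: float,
) -> tuple[float, float]:
    """Biomarker mean/variance by summing the daily convolution directly."""
    w = brute_weights(bk, t)
    mean_i = omega * math.exp(beta)
    var_i = omega * math.exp(alpha) + omega * (1 - omega) * math.exp(2 * beta)
    return float(w.sum() * mean_i), float((w**2).sum() * var_i + sigma_eps2)


def brute_cross_cov(
    omega: float,
    t1: int,
    t2: int,
    bk: BiokineticParams,
    alpha: float,
    beta: float,
) -> float:
    """Covariance of measurements at t1 <= t2 from the shared days j = 1..t1."""
    var_i = omega * math.exp(alpha) + omega * (1 - omega) * math.exp(2 * beta)
    j = np.arange(1, t1 + 1, dtype=float)
    w1 = (bk.f / bk.v) * np.exp(-bk.k * (t1 - j))
    w2 = (bk.f / bk.v) * np.exp(-bk.k * (t2 - j))
    return float((w1 * w2).sum() * var_i)


def make_dataset(
    n: int,
    omega,
    bk: BiokineticParams,
    y=None,
    t: int = T_STUDY,
    sigma_eps2: float = SIGMA_EPS2,
    ids=None,
    ts=None,
) -> BiomarkerDataset:
    """Hand-rolled dataset builder for estimator unit tests."""
    omega = np.broadcast_to(np.asarray(omega, dtype=float), (n,))
    return BiomarkerDataset(
        ids=np.arange(n) if ids is None else np.asarray(ids),
        y=np.zeros(n) if y is None else np.asarray(y, dtype=float),
        omega=omega,
        t=np.full(n, t) if ts is None else np.asarray(ts),
        f=np.full(n, bk.f),
        v=np.full(n, bk.v),
        k=np.full(n, bk.k),
        sigma_eps2=sigma_eps2,
    )
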