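"""Model-implied biomarker moments and estimating-equation ingredients.

For a biomarker that is a weighted sum of i.i.d. zero-inflated-gamma
daily intakes plus additive measurement error, the mean and covariance
of the observation vector have closed forms in the exposure parameters
(alpha, beta), the exposure frequency omega, and the biokinetic weight
sums S1/S2.  This module assembles, at a given parameter pair, every
quantity the alternating estimating equations need:

* ``EY``    -- mean vector; also the derivative D = dEY/dbeta, since the
  mean is proportional to e**beta.
* ``V``     -- covariance of Y: diagonal with one measurement per
  individual, block-diagonal by individual otherwise, with
  within-individual covariance from the shared exposure days.
* ``Dstar`` -- derivative of diag(V) with respect to alpha.
* ``V**``   -- working covariance of the squared-residual vector s
  under the independence working-matrix approximation: diagonal
  entries 2*V_ii, within-individual off-diagonal entries V_ii*V_jj.
  This is a deliberately crude weighting, not the exact normal-theory
  fourth moment (which would be 2*V_ii**2): with a shared design the
  weights cancel out of the point estimates entirely, while the
  model-based variance it implies for alpha_hat is inflated, making
  the plug-in intervals for sigma_g2 conservative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biokinetics import BiokineticParams

__all__ = [
    "BiomarkerDataset",
    "MomentSet",
    "expected_biomarker",
    "biomarker_variance",
    "repeated_measure_covariance",
    "assemble_moments",
]


def _geom_sums(k: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized S1, S2 (see :func:`nonsteady.biokinetics.weight_sums`)."""
    s1 = np.expm1(-k * t) / np.expm1(-k)
    s2 = np.expm1(-2.0 * k * t) / np.expm1(-2.0 * k)
    return s1, s2


@dataclass
class BiomarkerDataset:
    """Long-format biomarker observations with per-individual constants.

    One row per observation; individuals with repeated measurements
    appear in several rows and must share ``omega`` and biokinetics.
    ``sigma_eps2`` is the known measurement-error variance (ug**2/L**2),
    common to all observations.
    """

    ids: np.ndarray
    y: np.ndarray
    omega: np.ndarray
    t: np.ndarray
    f: np.ndarray
    v: np.ndarray
    k: np.ndarray
    sigma_eps2: float

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        for name in ("y", "omega", "t", "f", "v", "k"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.ids.shape[0]
        for name in ("y", "omega", "t", "f", "v", "k"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"field {name!r} must have shape ({n},)")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("biomarker values y must be finite")
        if np.any((self.omega < 0) | (self.omega > 1)):
            raise ValueError("omega must lie in [0, 1]")
        if np.any(self.t < 1):
            raise ValueError("measurement day t must be >= 1")
        if self.sigma_eps2 < 0:
            raise ValueError("sigma_eps2 must be non-negative")
        for uid in np.unique(self.ids):
            sel = self.ids == uid
            for name in ("omega", "f", "v", "k"):
                if np.unique(getattr(self, name)[sel]).size > 1:
                    raise ValueError(
                        f"individual {uid!r} has inconsistent {name!r} across rows"
                    )

    def __len__(self) -> int:
        return int(self.ids.shape[0])

    @property
    def has_repeats(self) -> bool:
        return len(np.unique(self.ids)) < len(self)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        sigma_eps2: float,
        defaults: BiokineticParams | None = None,
        default_t: int | None = None,
    ) -> "BiomarkerDataset":
        """Build a dataset from a long-format table.

        Required columns: ``id``, ``y``, ``omega``.  Optional columns
        ``t``, ``f``, ``v``, ``k`` fall back to ``default_t`` and
        ``defaults`` when absent.
        """
        bk = defaults if defaults is not None else BiokineticParams()
        n = len(frame)

        def col(name: str, fallback: float | None) -> np.ndarray:
            if name in frame.columns:
                return frame[name].to_numpy(dtype=float)
            if fallback is None:
                raise ValueError(f"missing column {name!r} and no default supplied")
            return np.full(n, float(fallback))

        return cls(
            ids=frame["id"].to_numpy(),
            y=frame["y"].to_numpy(dtype=float),
            omega=frame["omega"].to_numpy(dtype=float),
            t=col("t", default_t),
            f=col("f", bk.f),
            v=col("v", bk.v),
            k=col("k", bk.k),
            sigma_eps2=float(sigma_eps2),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "y": self.y,
                "omega": self.omega,
                "t": self.t.astype(int),
                "f": self.f,
                "v": self.v,
                "k": self.k,
            }
        )


@dataclass
class MomentSet:
    """Moments and derivatives at one (alpha, beta) pair.

    ``blocks`` lists, for each individual with repeated measurements,
    the observation indices together with the within-individual V and
    V** blocks; it is ``None`` when every individual contributes a
    single observation (purely diagonal case).
    """

    EY: np.ndarray
    Vdiag: np.ndarray
    D: np.ndarray
    Dstar: np.ndarray
    Vss_diag: np.ndarray
    blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = field(default=None)

    def dense_V(self) -> np.ndarray:
        """Full covariance matrix (for small-instance checks)."""
        V = np.diag(self.Vdiag)
        if self.blocks:
            for idx, Vb, _ in self.blocks:
                V[np.ix_(idx, idx)] = Vb
        return V

    def dense_Vss(self) -> np.ndarray:
        """Full working covariance of the squared residuals."""
        Vss = np.diag(self.Vss_diag)
        if self.blocks:
            for idx, _, Vssb in self.blocks:
                Vss[np.ix_(idx, idx)] = Vssb
        return Vss


def expected_biomarker(omega, t, bk: BiokineticParams, beta: float):
    """Model-implied biomarker mean: omega * e**beta * (f/v) * S1(t)."""
    omega = np.asarray(omega, dtype=float)
    t = np.asarray(t, dtype=float)
    s1, _ = _geom_sums(np.full_like(t, bk.k), t)
    out = omega * np.exp(beta) * (bk.f / bk.v) * s1
    return out if out.ndim else float(out)


def _unconditional_var(omega, alpha: float, beta: float):
    """Daily-intake variance omega*e^alpha + omega*(1-omega)*e^(2 beta)."""
    return omega * np.exp(alpha) + omega * (1.0 - omega) * np.exp(2.0 * beta)


def biomarker_variance(
    omega, t, bk: BiokineticParams, alpha: float, beta: float, sigma_eps2: float
):
    """Model-implied biomarker variance (single observation).

    ``(f/v)**2 * S2(t) * VarI + sigma_eps2`` where VarI is the
    unconditional daily-intake variance.
    """
    omega = np.asarray(omega, dtype=float)
    t = np.asarray(t, dtype=float)
    _, s2 = _geom_sums(np.full_like(t, bk.k), t)
    out = (bk.f / bk.v) ** 2 * s2 * _unconditional_var(omega, alpha, beta) + sigma_eps2
    return out if out.ndim else float(out)


def repeated_measure_covariance(
    omega, t1, t2, bk: BiokineticParams, alpha: float, beta: float
):
    """Covariance between measurements on days t1 <= t2 in one individual.

    Only exposures on the shared days j = 1..t1 contribute to both
    measurements, giving
    ``(f/v)**2 * e**(-k (t2 - t1)) * S2(t1) * VarI``.
    Measurement errors are independent, so ``sigma_eps2`` enters the
    diagonal only.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t1 > t2):
        raise ValueError("repeated_measure_covariance requires t1 <= t2")
    omega = np.asarray(omega, dtype=float)
    _, s2 = _geom_sums(np.full_like(t1, bk.k), t1)
    out = (
        (bk.f / bk.v) ** 2
        * np.exp(-bk.k * (t2 - t1))
        * s2
        * _unconditional_var(omega, alpha, beta)
    )
    return out if out.ndim else float(out)


def assemble_moments(data: BiomarkerDataset, alpha: float, beta: float) -> MomentSet:
    """Evaluate EY, V, D, D*, and V** at (alpha, beta) for a dataset."""
    s1, s2 = _geom_sums(data.k, data.t)
    c1 = (data.f / data.v) * s1
    c2 = (data.f / data.v) ** 2 * s2

    e_beta = np.exp(beta)
    EY = data.omega * e_beta * c1
    var_i = _unconditional_var(data.omega, alpha, beta)
    Vdiag = c2 * var_i + data.sigma_eps2
    D = EY.copy()  # dEY/dbeta = EY for the single-parameter log-mean model
    Dstar = c2 * data.omega * np.exp(alpha)  # dV_ii/dalpha
    Vss_diag = 2.0 * Vdiag  # crude working weight for s (see module docstring)

    blocks = None
    if data.has_repeats:
        blocks = []
        for uid in np.unique(data.ids):
            idx = np.flatnonzero(data.ids == uid)
            if idx.size < 2:
                continue
            order = idx[np.argsort(data.t[idx], kind="stable")]
            tt = data.t[order]
            bk = BiokineticParams(
                f=float(data.f[order[0]]),
                v=float(data.v[order[0]]),
                k=float(data.k[order[0]]),
            )
            om = float(data.omega[order[0]])
            m = order.size
            Vb = np.empty((m, m))
            for a in range(m):
                for b in range(a, m):
                    if a == b:
                        Vb[a, a] = Vdiag[order[a]]
                    else:
                        Vb[a, b] = Vb[b, a] = repeated_measure_covariance(
                            om, tt[a], tt[b], bk, alpha, beta
                        )
            vd = Vdiag[order]
            Vssb = np.outer(vd, vd)
            np.fill_diagonal(Vssb, 2.0 * vd**2)
            blocks.append((order, Vb, Vssb))
        if not blocks:
            blocks = None

    return MomentSet(EY=EY, Vdiag=Vdiag, D=D, Dstar=Dstar, Vss_diag=Vss_diag, blocks=blocks)
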