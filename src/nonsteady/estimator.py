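"""Alternating quasi-likelihood estimating equations for (beta, alpha).

The mean of the biomarker vector depends on the single parameter
``beta`` (log conditional mean intake) and its covariance additionally
on ``alpha`` (log conditional intake variance).  Each parameter has its
own estimating equation:

* beta: the quasi-score ``D' V^-1 (Y - EY) = 0``;
* alpha: ``D*' V**^-1 (s - diag V) = 0`` where ``s`` holds the squared
  residuals at the current mean and ``V**`` is the working covariance
  of ``s`` from an independence/normality approximation.

Both are solved by Fisher-scored Newton updates, alternating one beta
step and one alpha step per outer iteration until the natural-scale
estimates ``mu = e**beta`` and ``sigma_g2 = e**alpha`` stabilize.
Judging convergence on the natural scale matters: with few individuals
or rare exposures the alpha equation may have no interior root, in
which case the iteration drives ``sigma_g2`` to the boundary at zero
(``alpha -> -inf``).  These boundary fits are legitimate converged
estimates of a non-negative variance, not failures; fits are flagged
non-converged only when the iteration cap is hit or an iterate becomes
non-finite.

Model-based variance estimates ``(D' V^-1 D)^-1`` and
``(D*' V**^-1 D*)^-1`` fall out of the final iteration and feed
normal-theory confidence intervals on the log scale, exponentiated to
the natural scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .moments import BiomarkerDataset, MomentSet, assemble_moments

__all__ = [
    "FitOptions",
    "EEFit",
    "InestimableParameterError",
    "beta_step",
    "alpha_step",
    "beta_quasi_score",
    "alpha_quasi_score",
    "fit",
    "confidence_interval",
]

#: per-iteration caps on the Newton steps (log scale).  A step taken from
#: far below the root on these exponential mean/variance surfaces
#: overshoots by a factor ~e**distance; damping keeps the iterates finite
#: and never binds in the neighborhood of the solution.
_MAX_BETA_STEP = 10.0
_MAX_ALPHA_STEP = 30.0


class InestimableParameterError(ValueError):
    """Raised when the data carry no information on a parameter
    (e.g. every individual has exposure frequency zero)."""


@dataclass(frozen=True)
class FitOptions:
    """Controls for the alternating estimating-equations solver.

    ``tol`` is an absolute tolerance on the change in the natural-scale
    estimates (mu, sigma_g2) between successive outer iterations.
    ``fix_alpha`` switches to external-estimate mode: alpha is held at
    the supplied value and only beta is estimated.  ``sigma_eps2``, when
    given, overrides the dataset's measurement-error variance.
    """

    tol: float = 1e-8
    max_iter: int = 100
    init_beta: float | None = None
    init_alpha: float | None = None
    fix_alpha: float | None = None
    sigma_eps2: float | None = None

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass
class EEFit:
    """Result of an alternating estimating-equations fit."""

    beta_hat: float
    alpha_hat: float
    var_beta: float
    var_alpha: float
    converged: bool
    n_iter: int
    trace: np.ndarray  # (n_iter + 1, 2) array of (beta, alpha) iterates
    sigma_eps2: float
    n_obs: int
    alpha_fixed: bool = field(default=False)

    @property
    def mu_hat(self) -> float:
        """Estimated mean exposure magnitude e**beta_hat (ug d**-1)."""
        return math.exp(self.beta_hat)

    @property
    def sigma_g2_hat(self) -> float:
        """Estimated exposure-magnitude variance e**alpha_hat (ug**2 d**-2)."""
        return math.exp(self.alpha_hat) if math.isfinite(self.alpha_hat) else 0.0

    @property
    def se_beta(self) -> float:
        return math.sqrt(self.var_beta)

    @property
    def se_alpha(self) -> float:
        return math.sqrt(self.var_alpha)


def _quad(
    moments: MomentSet,
    d: np.ndarray,
    resid: np.ndarray,
    which: str,
) -> tuple[float, float]:
    """Return (d' W^-1 resid, d' W^-1 d) with W = V or V** by blocks.

    Uses the summation-over-block-diagonal form: purely diagonal
    observations contribute scalar terms; individuals with repeated
    measurements contribute small dense solves.
    """
    wdiag = moments.Vdiag if which == "V" else moments.Vss_diag
    in_block = np.zeros(d.shape[0], dtype=bool)
    num = den = 0.0
    if moments.blocks:
        for idx, Vb, Vssb in moments.blocks:
            in_block[idx] = True
            W = Vb if which == "V" else Vssb
            sol = np.linalg.solve(W, np.column_stack([resid[idx], d[idx]]))
            num += float(d[idx] @ sol[:, 0])
            den += float(d[idx] @ sol[:, 1])
    free = ~in_block
    with np.errstate(divide="ignore", invalid="ignore"):
        wi = np.where(wdiag[free] > 0, 1.0 / wdiag[free], 0.0)
    num += float(np.sum(d[free] * resid[free] * wi))
    den += float(np.sum(d[free] ** 2 * wi))
    return num, den


def beta_quasi_score(data: BiomarkerDataset, alpha: float, beta: float) -> float:
    """Quasi-score D' V^-1 (Y - EY) for beta; zero at the estimate."""
    mom = assemble_moments(data, alpha, beta)
    num, _ = _quad(mom, mom.D, data.y - mom.EY, "V")
    return num


def alpha_quasi_score(data: BiomarkerDataset, alpha: float, beta: float) -> float:
    """Estimating function D*' V**^-1 (s - diag V) for alpha."""
    mom = assemble_moments(data, alpha, beta)
    s = (data.y - mom.EY) ** 2
    num, _ = _quad(mom, mom.Dstar, s - mom.Vdiag, "Vss")
    return num


def beta_step(data: BiomarkerDataset, moments: MomentSet, beta_l: float) -> float:
    """One Fisher-scored Newton update of beta.

    ``beta_{l+1} = beta_l + (D'V^-1 D)^-1 D'V^-1 (Y - EY)`` with all
    quantities evaluated at the current iterate.
    """
    num, den = _quad(moments, moments.D, data.y - moments.EY, "V")
    if not np.isfinite(den) or den <= 0.0:
        raise InestimableParameterError(
            "beta is inestimable: D'V^-1 D is singular (all exposure "
            "frequencies zero or degenerate variances)"
        )
    return beta_l + float(np.clip(num / den, -_MAX_BETA_STEP, _MAX_BETA_STEP))


def alpha_step(data: BiomarkerDataset, moments: MomentSet, alpha_l: float) -> float:
    """One Fisher-scored Newton update of alpha.

    Uses the squared residuals ``s_i = (Y_i - EY_i)**2`` at the current
    mean.  A non-finite update is returned as ``nan`` (divergence is
    tallied by the caller, not raised) and the raw step is capped to
    avoid overflow of e**alpha.
    """
    s = (data.y - moments.EY) ** 2
    num, den = _quad(moments, moments.Dstar, s - moments.Vdiag, "Vss")
    if not np.isfinite(num) or not np.isfinite(den) or den <= 0.0:
        return math.nan
    step = num / den
    return alpha_l + float(np.clip(step, -_MAX_ALPHA_STEP, _MAX_ALPHA_STEP))


def _initial_values(
    data: BiomarkerDataset, options: FitOptions
) -> tuple[float, float]:
    """Cheap consistent starting values.

    beta0 comes from the frequency-corrected steady-state estimate
    b*y/omega averaged over observations; alpha0 from a method-of-
    moments inversion of the residual variance, floored at 5% of the
    squared conditional mean so the variance iteration starts at (or
    above) the scale of its root.
    """
    b = data.k * data.v / data.f
    base = float(np.mean(b * data.y / data.omega))
    if not math.isfinite(base) or base <= 0.0:
        base = max(float(np.mean(np.abs(b * data.y))), 1e-8)
    beta0 = float(np.clip(math.log(base), -30.0, 30.0))
    if options.init_beta is not None:
        beta0 = options.init_beta

    if options.fix_alpha is not None:
        return beta0, options.fix_alpha
    if options.init_alpha is not None:
        return beta0, options.init_alpha

    mom0 = assemble_moments(data, 0.0, beta0)
    c2 = mom0.Dstar  # equals (f/v)^2 S2 * omega at alpha = 0
    r2 = (data.y - mom0.EY) ** 2
    e2b = math.exp(2.0 * beta0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_i = (r2 - data.sigma_eps2) / c2 - (1.0 - data.omega) * e2b
    x0 = float(np.mean(x_i))
    x0 = max(x0, 0.05 * e2b)
    alpha0 = float(np.clip(math.log(x0), -30.0, 30.0))
    return beta0, alpha0


def fit(data: BiomarkerDataset, options: FitOptions | None = None) -> EEFit:
    """Fit (beta, alpha) by alternating estimating equations.

    Observations with ``omega = 0`` carry no information on either
    parameter and are dropped before fitting.  Returns a completed
    :class:`EEFit`; non-convergence is reported through the
    ``converged`` flag rather than an exception so that Monte-Carlo
    harnesses can tabulate convergence rates.
    """
    options = options or FitOptions()
    if len(data) == 0:
        raise ValueError("cannot fit an empty dataset")
    if options.sigma_eps2 is not None:
        data = replace(data, sigma_eps2=float(options.sigma_eps2))
    keep = data.omega > 0
    if not np.any(keep):
        raise InestimableParameterError(
            "all observations have omega = 0; beta is inestimable"
        )
    if not np.all(keep):
        data = BiomarkerDataset(
            ids=data.ids[keep],
            y=data.y[keep],
            omega=data.omega[keep],
            t=data.t[keep],
            f=data.f[keep],
            v=data.v[keep],
            k=data.k[keep],
            sigma_eps2=data.sigma_eps2,
        )

    alpha_fixed = options.fix_alpha is not None
    beta, alpha = _initial_values(data, options)
    trace = [(beta, alpha)]
    converged = False
    n_iter = 0
    mom = assemble_moments(data, alpha, beta)

    for n_iter in range(1, options.max_iter + 1):
        beta_new = beta_step(data, mom, beta)
        if not math.isfinite(beta_new):
            break
        mom = assemble_moments(data, alpha, beta_new)
        if alpha_fixed:
            alpha_new = alpha
        else:
            alpha_new = alpha_step(data, mom, alpha)
            if not math.isfinite(alpha_new):
                break
            mom = assemble_moments(data, alpha_new, beta_new)
        trace.append((beta_new, alpha_new))
        d_mu = abs(math.exp(beta_new) - math.exp(beta))
        d_sig = abs(math.exp(alpha_new) - math.exp(alpha))
        beta, alpha = beta_new, alpha_new
        if max(d_mu, d_sig) < options.tol:
            converged = True
            break

    _, var_beta = _quad(mom, mom.D, mom.EY, "V")
    var_beta = 1.0 / var_beta if var_beta > 0 else math.inf
    if alpha_fixed:
        var_alpha = 0.0
    else:
        _, den_a = _quad(mom, mom.Dstar, mom.Dstar, "Vss")
        var_alpha = 1.0 / den_a if den_a > 0 else math.inf

    return EEFit(
        beta_hat=beta,
        alpha_hat=alpha,
        var_beta=var_beta,
        var_alpha=var_alpha,
        converged=converged,
        n_iter=n_iter,
        trace=np.asarray(trace),
        sigma_eps2=data.sigma_eps2,
        n_obs=len(data),
        alpha_fixed=alpha_fixed,
    )


def confidence_interval(
    fit_result: EEFit, level: float = 0.95
) -> dict[str, tuple[float, float]]:
    """Plug-in confidence intervals for mu and sigma_g2.

    Normal-theory intervals on the log scale, exponentiated:
    ``exp(estimate +- z * SE)``.  Requires a converged fit.  In
    external-estimate mode (alpha fixed) the sigma_g2 interval is the
    degenerate point interval at the supplied value.
    """
    if not fit_result.converged:
        raise ValueError("confidence intervals require a converged fit")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    z = float(stats.norm.ppf(0.5 * (1.0 + level)))
    hw_b = z * fit_result.se_beta
    out = {
        "mu": (
            math.exp(fit_result.beta_hat - hw_b),
            math.exp(fit_result.beta_hat + hw_b),
        )
    }
    if fit_result.alpha_fixed:
        out["sigma_g2"] = (fit_result.sigma_g2_hat, fit_result.sigma_g2_hat)
    else:
        hw_a = z * fit_result.se_alpha
        lo = fit_result.alpha_hat - hw_a
        hi = fit_result.alpha_hat + hw_a
        out["sigma_g2"] = (
            math.exp(lo) if lo < 700 else math.inf,
            math.exp(hi) if hi < 700 else math.inf,
        )
    return out
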