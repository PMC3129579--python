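"""Reading biomarker tables and writing fit reports.

The input is a single long-format delimited table, one row per
biomarker observation, which accommodates both one and several
measurements per individual without a schema change.  Required columns
are ``id``, ``y`` (ug/L) and ``omega`` (day**-1); ``t``, ``f``, ``v``
and ``k`` are optional and fall back to configured defaults.  Fit
reports are JSON with full provenance (options, seed, package version)
so a written report can be re-parsed to the exact estimates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .biokinetics import BiokineticParams
from .estimator import EEFit, FitOptions, confidence_interval
from .moments import BiomarkerDataset

__all__ = ["TableValidationError", "read_biomarker_table", "write_fit_report", "read_fit_report"]

_REQUIRED = ("id", "y", "omega")
_OPTIONAL = ("t", "f", "v", "k")


class TableValidationError(ValueError):
    """A biomarker table failed validation; the message names the
    offending row (1-based, excluding the header) and column."""


def read_biomarker_table(
    path: str | Path,
    sigma_eps2: float,
    defaults: BiokineticParams | None = None,
    default_t: int | None = None,
) -> BiomarkerDataset:
    """Load and validate a CSV/TSV biomarker table.

    The delimiter is taken from the file extension (``.tsv`` -> tab,
    otherwise comma).  Missing optional columns are filled from
    ``defaults`` / ``default_t``; validation failures raise
    :class:`TableValidationError` naming the row and column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)

    for col in _REQUIRED:
        if col not in frame.columns:
            raise TableValidationError(f"missing required column {col!r}")

    for col in _REQUIRED[1:] + tuple(c for c in _OPTIONAL if c in frame.columns):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if frame[col].isna().any() or bad.any():
            row = int((frame[col].isna() | bad).idxmax()) + 1
            raise TableValidationError(
                f"non-numeric or missing value in column {col!r} at row {row}"
            )
        frame[col] = numeric

    out_of_range = (frame["omega"] < 0) | (frame["omega"] > 1)
    if out_of_range.any():
        row = int(out_of_range.idxmax()) + 1
        raise TableValidationError(
            f"omega outside [0, 1] in column 'omega' at row {row}"
        )

    if "t" in frame.columns:
        dup = frame.duplicated(subset=["id", "t"])
        if dup.any():
            row = int(dup.idxmax()) + 1
            raise TableValidationError(
                f"duplicate (id, t) pair at row {row}: repeated measurements "
                "must be taken on distinct days"
            )
    elif frame.duplicated(subset=["id"]).any():
        row = int(frame.duplicated(subset=["id"]).idxmax()) + 1
        raise TableValidationError(
            f"duplicate id at row {row} without a 't' column to distinguish "
            "measurement days"
        )

    try:
        return BiomarkerDataset.from_frame(
            frame, sigma_eps2=sigma_eps2, defaults=defaults, default_t=default_t
        )
    except ValueError as exc:  # e.g. t missing with no default
        raise TableValidationError(str(exc)) from exc


def write_fit_report(
    fit_result: EEFit,
    path: str | Path,
    options: FitOptions | None = None,
    seed: int | None = None,
    level: float = 0.95,
) -> dict:
    """Write a machine-readable JSON fit report; returns the record.

    Confidence intervals are included only for converged fits.
    """
    from . import __version__

    record: dict = {
        "package": "nonsteady",
        "version": __version__,
        "converged": bool(fit_result.converged),
        "n_iter": int(fit_result.n_iter),
        "n_obs": int(fit_result.n_obs),
        "sigma_eps2": float(fit_result.sigma_eps2),
        "alpha_fixed": bool(fit_result.alpha_fixed),
        "estimates": {
            "beta_hat": fit_result.beta_hat,
            "alpha_hat": fit_result.alpha_hat,
            "mu_hat": fit_result.mu_hat,
            "sigma_g2_hat": fit_result.sigma_g2_hat,
            "se_beta": fit_result.se_beta,
            "se_alpha": fit_result.se_alpha,
        },
    }
    if fit_result.converged:
        ci = confidence_interval(fit_result, level)
        record["confidence_intervals"] = {
            "level": level,
            "mu": list(ci["mu"]),
            "sigma_g2": [x if np.isfinite(x) else None for x in ci["sigma_g2"]],
        }
    if options is not None:
        record["options"] = {
            "tol": options.tol,
            "max_iter": options.max_iter,
            "init_beta": options.init_beta,
            "init_alpha": options.init_alpha,
            "fix_alpha": options.fix_alpha,
            "sigma_eps2": options.sigma_eps2,
        }
    if seed is not None:
        record["seed"] = int(seed)

    Path(path).write_text(json.dumps(record, indent=2) + "\n")
    return record


def read_fit_report(path: str | Path) -> dict:
    """Re-parse a written fit report."""
    return json.loads(Path(path).read_text())
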