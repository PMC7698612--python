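"""Spectrum fitting and temperature-determination accuracy.

A measured or simulated spectrum is fit with the double-Lorentzian line shape
by nonlinear least squares; the fitted zero-field splitting ``D_obs`` and its
standard error are the thermometry observables.  Accuracy in K/Hz^1/2 is
computed two ways, mirroring how repeated sweep measurements are evaluated:

* ``sd_of_repeats``: the standard deviation of ``D_obs`` over repeated
  sweeps, converted to kelvin via |dD/dT| = 77 kHz/K and normalized by the
  square root of the sweep time;
* ``fit_error``: the standard error of ``D`` from a single fit's covariance,
  normalized the same way.

For 1-second sweeps the kelvin and K/Hz^1/2 numbers coincide.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from . import _batchfit
from .spectral_model import (
    DEFAULT_CONSTANTS,
    LorentzianParams,
    Spectrum,
    ThermometryConstants,
    _evaluate_raw,
)

__all__ = [
    "FitResult",
    "AccuracyRecord",
    "fit_spectrum",
    "fit_replicates",
    "accuracy_from_series",
    "accuracy_from_fit_error",
]

AccuracyMethod = Literal["sd_of_repeats", "fit_error"]


@dataclass
class FitResult:
    """Outcome of fitting one spectrum.

    ``d_obs`` duplicates ``params.D`` for convenience; ``std_errors`` are the
    per-parameter standard errors [D, E, a1, a2, gamma] from the local
    curvature of the least-squares objective.
    """

    params: LorentzianParams
    std_errors: np.ndarray
    converged: bool
    residual_rms: float
    n_points: int

    @property
    def d_obs(self) -> float:
        return self.params.D

    @property
    def se_d(self) -> float:
        return float(self.std_errors[0])

    def to_json(self) -> str:
        payload = {
            "params": asdict(self.params),
            "std_errors": [float(s) for s in self.std_errors],
            "converged": bool(self.converged),
            "residual_rms": float(self.residual_rms),
            "n_points": int(self.n_points),
        }
        return json.dumps(payload)


@dataclass
class AccuracyRecord:
    """A temperature-determination accuracy in K/Hz^1/2 (smaller is better)."""

    value: float
    method: AccuracyMethod
    sweep_time: float
    n_repeats: Optional[int] = None
    source: Optional[str] = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("sd_of_repeats", "fit_error"):
            raise ValueError(f"unknown accuracy method {self.method!r}")
        if self.value < 0:
            raise ValueError("accuracy must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _clip_params_for_storage(p: np.ndarray) -> LorentzianParams:
    """Build LorentzianParams from a raw fitted vector, clipping a hair inside
    the open dip-depth bound if the optimizer landed on it."""
    D, E, a1, a2, g = (float(x) for x in p)
    cap = 0.999999 * g * math.pi
    return LorentzianParams(
        D=D, E=max(E, 0.0), a1=min(max(a1, 0.0), cap), a2=min(max(a2, 0.0), cap),
        gamma=g,
    )


def fit_spectrum(spectrum: Spectrum, init: Union[str, np.ndarray] = "auto") -> FitResult:
    """Least-squares fit of one spectrum with the double-Lorentzian model.

    ``init`` is either "auto" (D from the smoothed minimum, E/gamma from the
    ensemble priors) or an explicit [D, E, a1, a2, gamma] start vector.
    Never raises on a bad fit: non-convergence is reported via the
    ``converged`` flag so batch pipelines can count and exclude.
    """
    omega = spectrum.frequencies
    data = np.asarray(spectrum.intensities, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("spectrum intensities must be finite")

    if isinstance(init, str):
        if init != "auto":
            raise ValueError(f"unknown init strategy {init!r}")
        p0 = _batchfit.initial_guess(omega, data[None, :])[0]
    else:
        p0 = np.asarray(init, dtype=float)
    lb, ub = _batchfit.default_bounds(omega)
    p0 = np.clip(p0, lb, ub)

    def residual(p: np.ndarray) -> np.ndarray:
        return _evaluate_raw(p, omega) - data

    def jacobian(p: np.ndarray) -> np.ndarray:
        _, J = _batchfit.model_and_jacobian(p[None, :], omega)
        return J[0]

    try:
        sol = least_squares(
            residual, p0, jac=jacobian, bounds=(lb, ub), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    except Exception:
        return FitResult(
            params=_clip_params_for_storage(p0),
            std_errors=np.full(5, np.nan),
            converged=False,
            residual_rms=float("nan"),
            n_points=len(data),
        )

    p = sol.x
    dof = max(len(data) - 5, 1)
    s2 = 2.0 * sol.cost / dof
    JtJ = sol.jac.T @ sol.jac
    converged = bool(sol.success)
    try:
        cov = np.linalg.inv(JtJ)
        var = np.diag(cov) * s2
        se = np.sqrt(var) if np.all(var >= 0) else np.full(5, np.nan)
    except np.linalg.LinAlgError:
        se = np.full(5, np.nan)
    if not np.all(np.isfinite(se)):
        converged = False
    depth = max(p[2], p[3]) / (p[4] * math.pi)
    if depth < _batchfit.MIN_INFORMATIVE_DEPTH:
        converged = False  # flat spectrum: D carries no information
    rms = math.sqrt(2.0 * sol.cost / len(data))
    return FitResult(
        params=_clip_params_for_storage(p),
        std_errors=se,
        converged=converged,
        residual_rms=rms,
        n_points=len(data),
    )


def fit_replicates(omega: np.ndarray, data: np.ndarray) -> _batchfit.BatchFitResult:
    """Fit many same-grid spectra at once (rows of ``data``).

    Thin public wrapper over the vectorized Levenberg-Marquardt used by the
    Monte Carlo sweep-range machinery.
    """
    return _batchfit.fit_batch(np.asarray(omega, dtype=float), data)


def accuracy_from_series(
    d_obs_series: Sequence[float],
    sweep_time: float,
    constants: ThermometryConstants = DEFAULT_CONSTANTS,
    source: Optional[str] = None,
) -> AccuracyRecord:
    """Accuracy from the spread of repeated D determinations.

    ``value = (SD(D_obs) / |dD/dT|) * sqrt(sweep_time)``.  NaN entries
    (non-converged fits) are excluded and counted; fewer than 2 usable
    entries is an error.
    """
    if sweep_time <= 0:
        raise ValueError("sweep_time must be positive")
    series = np.asarray(d_obs_series, dtype=float)
    usable = series[np.isfinite(series)]
    n_excluded = len(series) - len(usable)
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 converged D_obs values, got {len(usable)} "
            f"({n_excluded} excluded)"
        )
    sd_mhz = float(np.std(usable, ddof=1))
    value = sd_mhz / constants.dD_dT_magnitude * math.sqrt(sweep_time)
    return AccuracyRecord(
        value=value,
        method="sd_of_repeats",
        sweep_time=sweep_time,
        n_repeats=len(usable),
        source=source,
        n_excluded=n_excluded,
    )


def accuracy_from_fit_error(
    fit: FitResult,
    sweep_time: float,
    constants: ThermometryConstants = DEFAULT_CONSTANTS,
    source: Optional[str] = None,
) -> AccuracyRecord:
    """Accuracy from a single fit's standard error of D.

    ``value = (SE(D) / |dD/dT|) * sqrt(sweep_time)``.  Requires a converged fit.
    """
    if not fit.converged:
        raise ValueError("accuracy_from_fit_error requires a converged fit")
    if sweep_time <= 0:
        raise ValueError("sweep_time must be positive")
    value = fit.se_d / constants.dD_dT_magnitude * math.sqrt(sweep_time)
    return AccuracyRecord(
        value=value, method="fit_error", sweep_time=sweep_time, source=source
    )
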