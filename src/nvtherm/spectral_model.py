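"""ODMR line-shape model and thermometry conversions for NV-center nanodiamonds.

The ground-state spin resonance of an ensemble of nitrogen-vacancy (NV)
centers, read out optically while a microwave frequency ``omega`` is swept,
appears as two Lorentzian fluorescence dips centered at ``D + E`` and
``D - E``:

    I(omega) = 1 - (a1 / (gamma * pi)) / (1 + ((omega - D - E) / gamma)^2)
                 - (a2 / (gamma * pi)) / (1 + ((omega - D + E) / gamma)^2)

where ``D`` is the axial zero-field splitting (~2870 MHz), ``E`` the rhombic
splitting, ``gamma`` the half-width at half-maximum shared by both dips, and
``a1``, ``a2`` amplitude coefficients such that the fractional dip depths are
``a1/(gamma*pi)`` and ``a2/(gamma*pi)``.  ``D`` shifts with temperature at
|dD/dT| = 77 kHz/K, which is what makes the fitted ``D`` a thermometer.

This module owns the line-shape evaluation, the digital-sweep grid
convention, the D-shift -> temperature-shift conversion, and the plain-text
spectrum serialization used throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np

__all__ = [
    "LorentzianParams",
    "SweepGrid",
    "Spectrum",
    "ThermometryConstants",
    "DEFAULT_CONSTANTS",
    "MEAN_PARAMS",
    "evaluate_spectrum",
    "d_shift_to_temperature_shift",
    "signal_halfwidth",
]

#: Seconds of integration per digital-sweep point (50 points -> 1 s sweep).
DEFAULT_SECONDS_PER_POINT = 0.02


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class LorentzianParams:
    """Line-shape parameters of one emitter (all frequencies in MHz).

    ``a1`` scales the dip at ``D + E``; ``a2`` the dip at ``D - E``.
    Amplitudes have MHz units so that the dimensionless dip depths are
    ``a1 / (gamma * pi)`` and ``a2 / (gamma * pi)``.
    """

    D: float
    E: float
    a1: float
    a2: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("D", "E", "a1", "a2", "gamma"):
            _require_finite(name, getattr(self, name))
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if self.E < 0:
            raise ValueError(f"E must be >= 0, got {self.E}")
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("amplitudes a1, a2 must be >= 0")
        d1, d2 = self.dip_depths
        if d1 >= 1.0 or d2 >= 1.0:
            raise ValueError(
                f"dip depths a/(gamma*pi) must lie in [0, 1); got {d1:.3g}, {d2:.3g}"
            )

    @property
    def dip_depths(self) -> tuple[float, float]:
        """Fractional depths of the upper- and lower-frequency dips."""
        scale = 1.0 / (self.gamma * math.pi)
        return self.a1 * scale, self.a2 * scale

    def as_array(self) -> np.ndarray:
        return np.array([self.D, self.E, self.a1, self.a2, self.gamma], dtype=float)

    @classmethod
    def from_array(cls, p: Iterable[float]) -> "LorentzianParams":
        D, E, a1, a2, gamma = (float(x) for x in p)
        return cls(D=D, E=E, a1=a1, a2=a2, gamma=gamma)


#: Ensemble-mean line-shape parameters measured over ~200 nanodiamond spots.
MEAN_PARAMS = LorentzianParams(D=2869.34, E=4.21, a1=0.72, a2=0.80, gamma=5.07)


@dataclass(frozen=True)
class SweepGrid:
    """Evenly spaced digital-sweep frequency grid (half-open convention).

    The grid holds ``n_points`` frequencies ``f_k = f_start + k * spacing``
    for ``k = 0 .. n_points - 1`` with ``spacing = (f_end - f_start) /
    n_points``; ``f_end`` itself is not sampled.  This convention makes a
    100-point sweep exactly decomposable into its two 50-point sub-sweeps
    with no interpolation.
    """

    f_start: float
    f_end: float
    n_points: int

    def __post_init__(self) -> None:
        _require_finite("f_start", self.f_start)
        _require_finite("f_end", self.f_end)
        if self.f_end <= self.f_start:
            raise ValueError("f_end must exceed f_start")
        if int(self.n_points) != self.n_points or self.n_points < 4:
            raise ValueError("n_points must be an integer >= 4")
        object.__setattr__(self, "n_points", int(self.n_points))

    @property
    def spacing(self) -> float:
        return (self.f_end - self.f_start) / self.n_points

    @property
    def frequencies(self) -> np.ndarray:
        return self.f_start + self.spacing * np.arange(self.n_points)

    @property
    def center(self) -> float:
        return 0.5 * (self.f_start + self.f_end)

    @classmethod
    def centered(cls, center: float, half_width: float, n_points: int) -> "SweepGrid":
        """Grid spanning ``center +/- half_width`` (the sweep-design variable)."""
        return cls(center - half_width, center + half_width, n_points)


@dataclass
class Spectrum:
    """One digital-sweep spectrum: grid, baseline-normalized intensities, sweep time."""

    grid: SweepGrid
    intensities: np.ndarray
    sweep_time: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or len(self.intensities) != self.grid.n_points:
            raise ValueError(
                f"intensities must be 1-D with {self.grid.n_points} entries, "
                f"got shape {self.intensities.shape}"
            )
        if not (math.isfinite(self.sweep_time) and self.sweep_time > 0):
            raise ValueError(f"sweep_time must be positive, got {self.sweep_time}")

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write ``frequency_mhz,intensity`` rows with a sweep-time comment."""
        lines = [f"# sweep_time_s={self.sweep_time!r}", "frequency_mhz,intensity"]
        for f, y in zip(self.frequencies, self.intensities):
            lines.append(f"{float(f)!r},{float(y)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "Spectrum":
        sweep_time = None
        freqs: list[float] = []
        vals: list[float] = []
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                if key.strip() == "sweep_time_s":
                    sweep_time = float(value)
                continue
            if line.lower().startswith("frequency_mhz"):
                continue
            f, _, y = line.partition(",")
            freqs.append(float(f))
            vals.append(float(y))
        if sweep_time is None:
            raise ValueError(f"{path}: missing '# sweep_time_s=' header")
        if len(freqs) < 4:
            raise ValueError(f"{path}: too few rows for a sweep grid")
        f0 = freqs[0]
        spacing = freqs[1] - freqs[0]
        grid = SweepGrid(f0, f0 + spacing * len(freqs), len(freqs))
        if not np.allclose(grid.frequencies, freqs, rtol=0, atol=1e-9 * abs(f0)):
            raise ValueError(f"{path}: frequencies are not evenly spaced")
        return cls(grid=grid, intensities=np.array(vals), sweep_time=sweep_time)


@dataclass(frozen=True)
class ThermometryConstants:
    """|dD/dT| of the NV zero-field splitting, MHz per kelvin."""

    dD_dT_magnitude: float = 0.077

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dD_dT_magnitude) and self.dD_dT_magnitude > 0):
            raise ValueError("dD_dT_magnitude must be a positive finite number")


DEFAULT_CONSTANTS = ThermometryConstants()


def evaluate_spectrum(
    params: LorentzianParams, frequencies: Union[np.ndarray, Iterable[float], float]
) -> np.ndarray:
    """Noiseless double-Lorentzian fluorescence intensity at ``frequencies`` (MHz).

    Values are dimensionless, baseline 1, dips at ``D + E`` (scaled by ``a1``)
    and ``D - E`` (scaled by ``a2``).
    """
    omega = np.asarray(frequencies, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ValueError("frequencies must be finite")
    return _evaluate_raw(params.as_array(), omega)


def _evaluate_raw(p: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Evaluate the line shape from a bare parameter vector [D, E, a1, a2, gamma].

    Shared with the fitting code, which works on unvalidated trial vectors.
    ``p`` may be (5,) or (B, 5) against ``omega`` of shape (N,).
    """
    p = np.asarray(p, dtype=float)
    batched = p.ndim == 2
    if batched:
        D, E, a1, a2, g = (p[:, i : i + 1] for i in range(5))
    else:
        D, E, a1, a2, g = p
    u1 = (omega - D - E) / g
    u2 = (omega - D + E) / g
    c = 1.0 / (math.pi * g)
    return 1.0 - a1 * c / (1.0 + u1 * u1) - a2 * c / (1.0 + u2 * u2)


def d_shift_to_temperature_shift(
    delta_D: float, constants: ThermometryConstants = DEFAULT_CONSTANTS
) -> float:
    """Convert a shift of the fitted D (MHz) into a temperature shift (K).

    D decreases as the lattice heats, so a negative ``delta_D`` maps to a
    positive temperature change: ``delta_T = -delta_D / |dD/dT|``.
    """
    delta_D = _require_finite("delta_D", delta_D)
    return -delta_D / constants.dD_dT_magnitude


def signal_halfwidth(params: LorentzianParams) -> float:
    """Overall half-width of the two-dip ODMR signal, ``2*gamma + 2*E`` (MHz)."""
    return 2.0 * params.gamma + 2.0 * params.E
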