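"""Synthetic ODMR spectra and wide-field image stacks with ground truth.

This module replaces the microscope: it draws line-shape parameters around
the ensemble statistics measured over ~200 nanodiamond bright spots
(D = 2869.34 +/- 1.31 MHz, E = 4.21 +/- 0.31 MHz, a1 = 0.72 +/- 0.16,
a2 = 0.80 +/- 0.23, gamma = 5.07 +/- 0.59 MHz), simulates digital-sweep
spectra with additive Gaussian noise expressed as a fraction of the ODMR
signal strength (the deeper dip depth ``max(a1, a2)/(gamma*pi)``), and
renders wide-field fluorescence stacks of diffraction-blurred bright spots
whose per-frame flux follows each spot's spectrum.  Every generator is a
pure function of (configuration, seed), and every stack ships with a
ground-truth sidecar so downstream detection/extraction/fitting stages can
be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.special import erf

from .spectral_model import (
    DEFAULT_SECONDS_PER_POINT,
    LorentzianParams,
    Spectrum,
    SweepGrid,
    evaluate_spectrum,
)
from .widefield_pipeline import ImageStack

__all__ = [
    "ParamDistribution",
    "NoiseModel",
    "SceneConfig",
    "SpotTruth",
    "GroundTruth",
    "draw_params",
    "simulate_spectrum",
    "simulate_replicates",
    "generate_widefield_stack",
]

RngLike = Union[int, np.random.Generator]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class ParamDistribution:
    """Independent Gaussian distributions of the five line-shape parameters.

    Defaults are the measured ensemble means and standard deviations.
    Draws violating the line-shape invariants (e.g. gamma <= 0) are rejected
    and redrawn.
    """

    mean_D: float = 2869.34
    sd_D: float = 1.31
    mean_E: float = 4.21
    sd_E: float = 0.31
    mean_a1: float = 0.72
    sd_a1: float = 0.16
    mean_a2: float = 0.80
    sd_a2: float = 0.23
    mean_gamma: float = 5.07
    sd_gamma: float = 0.59

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite")
            if f.name.startswith("sd_") and v < 0:
                raise ValueError(f"{f.name} must be >= 0")
        # means must themselves form a valid parameter set
        self.means()

    def means(self) -> LorentzianParams:
        return LorentzianParams(
            D=self.mean_D, E=self.mean_E, a1=self.mean_a1, a2=self.mean_a2,
            gamma=self.mean_gamma,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian intensity noise as a fraction of ODMR signal strength.

    ``level`` is the noise fraction (0-0.20 in the sweep-design study); the
    reference signal strength is the deeper dip depth ``max(a1, a2) /
    (gamma * pi)``, so the per-point noise SD is ``level * depth``.
    """

    level: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.level) and self.level >= 0):
            raise ValueError(f"noise level must be >= 0, got {self.level}")

    def sigma_for(self, params: LorentzianParams) -> float:
        return self.level * max(params.dip_depths)


def draw_params(
    dist: ParamDistribution, rng: RngLike, max_tries: int = 1000
) -> LorentzianParams:
    """One Gaussian draw per parameter, rejection-resampled until valid."""
    gen = _as_rng(rng)
    means = np.array(
        [dist.mean_D, dist.mean_E, dist.mean_a1, dist.mean_a2, dist.mean_gamma]
    )
    sds = np.array([dist.sd_D, dist.sd_E, dist.sd_a1, dist.sd_a2, dist.sd_gamma])
    for _ in range(max_tries):
        vec = gen.normal(means, sds)
        try:
            return LorentzianParams.from_array(vec)
        except ValueError:
            continue
    raise RuntimeError(
        f"no valid parameter draw in {max_tries} tries; distribution is degenerate"
    )


def simulate_spectrum(
    params: LorentzianParams,
    grid: SweepGrid,
    noise: NoiseModel,
    rng: RngLike,
    sweep_time: Optional[float] = None,
    seconds_per_point: float = DEFAULT_SECONDS_PER_POINT,
) -> Spectrum:
    """One noisy digital-sweep spectrum.

    Intensity = line shape + i.i.d. Gaussian(0, level * deeper dip depth).
    Sweep time defaults to ``n_points * 0.02 s`` (a 50-point sweep takes 1 s).
    """
    gen = _as_rng(rng)
    clean = evaluate_spectrum(params, grid.frequencies)
    sigma = noise.sigma_for(params)
    noisy = clean if sigma == 0 else clean + gen.normal(0.0, sigma, grid.n_points)
    if sweep_time is None:
        sweep_time = grid.n_points * seconds_per_point
    return Spectrum(grid=grid, intensities=noisy, sweep_time=sweep_time)


def simulate_replicates(
    params: LorentzianParams,
    grid: SweepGrid,
    noise: NoiseModel,
    n_replicates: int,
    rng: RngLike,
    normal_draws: Optional[np.ndarray] = None,
) -> np.ndarray:
    """(n_replicates, n_points) noisy intensities sharing one grid.

    ``normal_draws`` may supply pre-drawn standard normals of the same shape
    (common random numbers across sweep-range candidates); otherwise fresh
    draws come from ``rng``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    clean = evaluate_spectrum(params, grid.frequencies)
    sigma = noise.sigma_for(params)
    if normal_draws is None:
        z = _as_rng(rng).standard_normal((n_replicates, grid.n_points))
    else:
        z = np.asarray(normal_draws, dtype=float)
        if z.shape != (n_replicates, grid.n_points):
            raise ValueError(
                f"normal_draws must have shape {(n_replicates, grid.n_points)}"
            )
    return clean[None, :] + sigma * z


# ---------------------------------------------------------------------------
# wide-field scene generation


@dataclass(frozen=True)
class SceneConfig:
    """Layout and acquisition settings of one synthetic wide-field scene.

    Spatial defaults emulate a 20x wide-field view at 0.5 um/pixel with
    diffraction-scale (sigma = 0.5 um) spots; spectra ride on the standard
    2850-2890 MHz 100-point sweep so the two 50-point sub-sweeps can be
    composed downstream.
    """

    image_shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.5
    n_spots: int = 10
    psf_sigma_um: float = 0.5
    background: float = 100.0
    background_noise_sd: float = 0.5
    brightness: float = 1000.0
    params: ParamDistribution = field(default_factory=ParamDistribution)
    draw_params_per_spot: bool = True
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(level=0.05))
    grid: SweepGrid = field(default_factory=lambda: SweepGrid(2850.0, 2890.0, 100))
    n_repeats: int = 10
    roi_edge_um: float = 7.0
    min_separation_um: Optional[float] = None  # defaults to roi_edge_um
    d_jitter_sd: float = 0.0  # per-repeat Gaussian jitter of each spot's D, MHz
    seconds_per_point: float = DEFAULT_SECONDS_PER_POINT
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.psf_sigma_um <= 0:
            raise ValueError("pixel_size_um and psf_sigma_um must be positive")
        if self.n_spots < 0 or self.n_repeats < 1:
            raise ValueError("n_spots must be >= 0 and n_repeats >= 1")
        if self.background_noise_sd < 0 or self.brightness <= 0:
            raise ValueError("invalid background/brightness settings")

    @property
    def separation_um(self) -> float:
        return self.roi_edge_um if self.min_separation_um is None else self.min_separation_um


@dataclass
class SpotTruth:
    row: float
    col: float
    brightness: float
    params: LorentzianParams


@dataclass
class GroundTruth:
    """Everything needed to score detection/extraction/fitting on a stack."""

    spots: list[SpotTruth]
    noise_level: float
    grid: SweepGrid
    pixel_size_um: float
    d_jitter_sd: float
    seed: Optional[int]

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "seed": self.seed,
            "noise_level": self.noise_level,
            "pixel_size_um": self.pixel_size_um,
            "d_jitter_sd": self.d_jitter_sd,
            "grid": {
                "f_start": self.grid.f_start,
                "f_end": self.grid.f_end,
                "n_points": self.grid.n_points,
            },
            "spots": [
                {
                    "row": s.row,
                    "col": s.col,
                    "brightness": s.brightness,
                    "params": dataclasses.asdict(s.params),
                }
                for s in self.spots
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            spots=[
                SpotTruth(
                    row=s["row"],
                    col=s["col"],
                    brightness=s["brightness"],
                    params=LorentzianParams(**s["params"]),
                )
                for s in payload["spots"]
            ],
            noise_level=payload["noise_level"],
            grid=SweepGrid(**payload["grid"]),
            pixel_size_um=payload["pixel_size_um"],
            d_jitter_sd=payload["d_jitter_sd"],
            seed=payload["seed"],
        )


def _place_spots(
    scene: SceneConfig, gen: np.random.Generator, max_tries: int = 20000
) -> list[tuple[float, float]]:
    """Uniform placement with a minimum-separation rejection rule.

    The margin keeps every ROI fully inside the frame.
    """
    rows, cols = scene.image_shape
    margin = scene.roi_edge_um / scene.pixel_size_um / 2.0 + 1.0
    if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
        raise ValueError("image too small for the requested ROI edge")
    min_sep_px = scene.separation_um / scene.pixel_size_um
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < scene.n_spots:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {scene.n_spots} spots at separation >= "
                f"{scene.separation_um} um in a {rows}x{cols} image"
            )
        tries += 1
        r = gen.uniform(margin, rows - margin)
        c = gen.uniform(margin, cols - margin)
        if all(math.hypot(r - pr, c - pc) >= min_sep_px for pr, pc in placed):
            placed.append((r, c))
    return placed


def _pixel_integrated_psf(
    row: float, col: float, sigma_px: float, r0: int, r1: int, c0: int, c1: int
) -> np.ndarray:
    """Unit-flux Gaussian PSF integrated over each pixel of a window.

    Pixel (i, j) covers [i, i+1) x [j, j+1); the integral over it is a
    product of error-function differences, so total flux over the plane is
    exactly 1 and truncation at the window edge is the only loss.
    """
    s = sigma_px * math.sqrt(2.0)
    edges_r = np.arange(r0, r1 + 1) - row
    edges_c = np.arange(c0, c1 + 1) - col
    cdf_r = 0.5 * (1.0 + erf(edges_r / s))
    cdf_c = 0.5 * (1.0 + erf(edges_c / s))
    return np.outer(np.diff(cdf_r), np.diff(cdf_c))


def generate_widefield_stack(
    scene: SceneConfig, rng: RngLike
) -> tuple[ImageStack, GroundTruth]:
    """Render a synthetic acquisition: one frame per sweep point, per repeat.

    Each spot contributes ``brightness * I(omega_frame)`` photons spread over
    a pixel-integrated Gaussian PSF, where ``I`` is the spot's line shape
    (optionally with per-frame spectral noise); the background adds a
    constant level plus per-pixel Gaussian noise.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = _as_rng(rng)
    rows, cols = scene.image_shape
    n_pts = scene.grid.n_points
    n_frames = scene.n_repeats * n_pts
    freqs = scene.grid.frequencies
    dtype = np.dtype(scene.dtype)

    positions = _place_spots(scene, gen)
    spots: list[SpotTruth] = []
    for r, c in positions:
        p = (
            draw_params(scene.params, gen)
            if scene.draw_params_per_spot
            else scene.params.means()
        )
        spots.append(SpotTruth(row=r, col=c, brightness=scene.brightness, params=p))

    if scene.background_noise_sd > 0:
        stack = gen.standard_normal((n_frames, rows, cols), dtype=np.float32).astype(
            dtype, copy=False
        )
        stack *= dtype.type(scene.background_noise_sd)
        stack += dtype.type(scene.background)
    else:
        stack = np.full((n_frames, rows, cols), scene.background, dtype=dtype)

    sigma_px = scene.psf_sigma_um / scene.pixel_size_um
    half = max(int(math.ceil(6.0 * sigma_px)), 3)
    for spot in spots:
        if scene.d_jitter_sd > 0:
            d_per_repeat = spot.params.D + gen.normal(0.0, scene.d_jitter_sd, scene.n_repeats)
            flux_clean = np.concatenate(
                [
                    evaluate_spectrum(
                        dataclasses.replace(spot.params, D=float(d)), freqs
                    )
                    for d in d_per_repeat
                ]
            )
        else:
            flux_clean = np.tile(evaluate_spectrum(spot.params, freqs), scene.n_repeats)
        sigma = scene.noise.sigma_for(spot.params)
        flux = flux_clean if sigma == 0 else flux_clean + gen.normal(0.0, sigma, n_frames)
        flux = spot.brightness * flux

        r_int, c_int = int(round(spot.row)), int(round(spot.col))
        r0, r1 = max(r_int - half, 0), min(r_int + half + 1, rows)
        c0, c1 = max(c_int - half, 0), min(c_int + half + 1, cols)
        footprint = _pixel_integrated_psf(spot.row, spot.col, sigma_px, r0, r1, c0, c1)
        stack[:, r0:r1, c0:c1] += (
            flux[:, None, None] * footprint[None, :, :]
        ).astype(dtype, copy=False)

    image_stack = ImageStack(
        data=stack,
        grid=scene.grid,
        n_repeats=scene.n_repeats,
        pixel_size_um=scene.pixel_size_um,
        seconds_per_point=scene.seconds_per_point,
    )
    truth = GroundTruth(
        spots=spots,
        noise_level=scene.noise.level,
        grid=scene.grid,
        pixel_size_um=scene.pixel_size_um,
        d_jitter_sd=scene.d_jitter_sd,
        seed=int(seed) if seed is not None else None,
    )
    return image_stack, truth
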