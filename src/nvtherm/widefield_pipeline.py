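"""Wide-field ODMR image-stack analysis: spots -> spectra -> accuracies.

The acquisition produces a fluorescence frame per microwave-sweep point,
repeated many times.  This module finds bright nanodiamond spots in the
time-averaged image, integrates each spot's ROI frame-by-frame into
digital-sweep spectra, splits the standard 100-point 2850-2890 MHz sweep
into its narrow (2860-2880, every point of the central half) and wide
(2850-2890, every second point) 50-point sub-sweeps, fits both repeatedly,
and reports per-spot temperature-determination accuracies by the
SD-of-repeats and fit-error procedures, plus the narrow-vs-wide winner
tally.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .spectral_model import (
    DEFAULT_CONSTANTS,
    DEFAULT_SECONDS_PER_POINT,
    Spectrum,
    SweepGrid,
    ThermometryConstants,
    d_shift_to_temperature_shift,
)
from . import fitting
from .fitting import AccuracyRecord, accuracy_from_fit_error, accuracy_from_series

__all__ = [
    "ImageStack",
    "SpotROI",
    "SpotReport",
    "AnalyzeConfig",
    "StackSummary",
    "detect_bright_spots",
    "extract_spot_spectrum",
    "decompose_sweep",
    "analyze_stack",
]


@dataclass
class ImageStack:
    """frames x rows x cols fluorescence data plus the frame->frequency map.

    Frames are ordered sweep-by-sweep: frame ``i`` belongs to repeat
    ``i // n_points`` and carries frequency ``grid.frequencies[i % n_points]``.
    """

    data: np.ndarray
    grid: SweepGrid
    n_repeats: int
    pixel_size_um: float
    seconds_per_point: float = DEFAULT_SECONDS_PER_POINT

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be frames x rows x cols")
        if self.data.shape[0] != self.n_repeats * self.grid.n_points:
            raise ValueError(
                f"{self.data.shape[0]} frames != n_repeats ({self.n_repeats}) x "
                f"grid points ({self.grid.n_points})"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def frame_frequencies(self) -> np.ndarray:
        return np.tile(self.grid.frequencies, self.n_repeats)

    @property
    def sweep_time(self) -> float:
        """Duration of one full sweep, seconds."""
        return self.grid.n_points * self.seconds_per_point

    def mean_image(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def save(self, path: Union[str, Path]) -> None:
        """Multi-page TIFF plus a `<stem>.stack.json` acquisition sidecar."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.data, photometric="minisblack")
        meta = {
            "grid": {
                "f_start": self.grid.f_start,
                "f_end": self.grid.f_end,
                "n_points": self.grid.n_points,
            },
            "n_repeats": self.n_repeats,
            "pixel_size_um": self.pixel_size_um,
            "seconds_per_point": self.seconds_per_point,
        }
        path.with_suffix(".stack.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ImageStack":
        import tifffile

        path = Path(path)
        meta = json.loads(path.with_suffix(".stack.json").read_text())
        return cls(
            data=tifffile.imread(path),
            grid=SweepGrid(**meta["grid"]),
            n_repeats=meta["n_repeats"],
            pixel_size_um=meta["pixel_size_um"],
            seconds_per_point=meta.get("seconds_per_point", DEFAULT_SECONDS_PER_POINT),
        )


@dataclass(frozen=True)
class SpotROI:
    """One bright spot and its square integration window (default 7 um edge)."""

    spot_id: int
    center: tuple[int, int]  # (row, col), pixels
    roi_edge_um: float = 7.0

    def window_halfwidth(self, pixel_size_um: float) -> int:
        """Half-width of the odd-sized pixel window covering ``roi_edge_um``."""
        if self.roi_edge_um <= 0:
            raise ValueError("roi_edge_um must be positive")
        n_px = self.roi_edge_um / pixel_size_um
        edge = max(int(round((n_px - 1) / 2)) * 2 + 1, 1)
        return edge // 2

    def window_slices(
        self, pixel_size_um: float, shape: tuple[int, int]
    ) -> tuple[slice, slice]:
        h = self.window_halfwidth(pixel_size_um)
        r, c = self.center
        if r - h < 0 or c - h < 0 or r + h >= shape[0] or c + h >= shape[1]:
            raise ValueError(f"ROI of spot {self.spot_id} extends outside the image")
        return slice(r - h, r + h + 1), slice(c - h, c + h + 1)


def detect_bright_spots(
    mean_image: np.ndarray,
    pixel_size_um: float,
    threshold_sigmas: float = 5.0,
    min_separation_um: float = 7.0,
    roi_edge_um: float = 7.0,
    smooth_sigma_px: float = 1.0,
) -> list[SpotROI]:
    """Find bright spots in a time-averaged frame.

    Gaussian-smooth, then accept local maxima above ``median + threshold_sigmas
    * robust SD`` (robust SD = 1.4826 * MAD).  Candidates are ordered by
    brightness; dimmer candidates closer than ``min_separation_um`` to an
    accepted one are dropped, as are spots whose ROI would touch the border.
    """
    img = np.asarray(mean_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("mean_image must be 2-D")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if img.size == 0:
        return []

    smooth = ndimage.gaussian_filter(img, smooth_sigma_px)
    med = np.median(smooth)
    mad = np.median(np.abs(smooth - med))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        robust_sd = smooth.std() or np.inf
    threshold = med + threshold_sigmas * robust_sd

    local_max = smooth == ndimage.maximum_filter(smooth, size=3)
    candidates = np.argwhere(local_max & (smooth > threshold))
    if len(candidates) == 0:
        return []
    order = np.argsort(-smooth[candidates[:, 0], candidates[:, 1]])
    candidates = candidates[order]

    min_sep_px = min_separation_um / pixel_size_um
    h = SpotROI(0, (0, 0), roi_edge_um).window_halfwidth(pixel_size_um)
    accepted: list[tuple[int, int]] = []
    for r, c in candidates:
        if r - h < 0 or c - h < 0 or r + h >= img.shape[0] or c + h >= img.shape[1]:
            continue
        if all(math.hypot(r - ar, c - ac) >= min_sep_px for ar, ac in accepted):
            accepted.append((int(r), int(c)))
    return [
        SpotROI(spot_id=i, center=pos, roi_edge_um=roi_edge_um)
        for i, pos in enumerate(accepted)
    ]


def extract_spot_spectrum(
    stack: ImageStack, roi: SpotROI, repeat_index: int
) -> Spectrum:
    """ROI-integrated spectrum of one spot for one sweep repeat.

    The per-frame sum over the ROI window is normalized by its own
    off-resonance plateau — the mean of the top decile of values — so the
    baseline sits at ~1 regardless of spot brightness or background.
    """
    if not 0 <= repeat_index < stack.n_repeats:
        raise IndexError(
            f"repeat_index {repeat_index} out of range [0, {stack.n_repeats})"
        )
    rs, cs = roi.window_slices(stack.pixel_size_um, stack.data.shape[1:])
    n = stack.grid.n_points
    frames = stack.data[repeat_index * n : (repeat_index + 1) * n, rs, cs]
    series = frames.sum(axis=(1, 2)).astype(float)
    top = np.sort(series)[-max(1, n // 10) :]
    plateau = top.mean()
    if plateau <= 0:
        raise ValueError(f"spot {roi.spot_id}: non-positive ROI plateau")
    return Spectrum(
        grid=stack.grid, intensities=series / plateau, sweep_time=stack.sweep_time
    )


def decompose_sweep(spectrum100: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Split one full sweep into its narrow and wide half-duration sub-sweeps.

    For an n-point parent (n divisible by 4): the narrow sub-sweep takes the
    contiguous central n/2 points (indices n/4 .. 3n/4 - 1, parent spacing);
    the wide one every second point (indices 0, 2, ..., n-2, double spacing,
    full span).  Intensities are exact copies — no interpolation — and each
    sub-sweep inherits half the parent sweep time.  The standard 100-point
    2850-2890 MHz sweep yields 2860-2880 and 2850-2890 MHz 50-point grids.
    """
    n = spectrum100.grid.n_points
    if n % 4 != 0:
        raise ValueError(f"parent sweep must have n_points divisible by 4, got {n}")
    parent = spectrum100.grid
    half_time = spectrum100.sweep_time / 2.0

    lo, hi = n // 4, 3 * n // 4
    narrow_grid = SweepGrid(
        parent.f_start + lo * parent.spacing,
        parent.f_start + hi * parent.spacing,
        n // 2,
    )
    narrow = Spectrum(
        grid=narrow_grid,
        intensities=spectrum100.intensities[lo:hi].copy(),
        sweep_time=half_time,
    )
    wide_grid = SweepGrid(parent.f_start, parent.f_end, n // 2)
    wide = Spectrum(
        grid=wide_grid,
        intensities=spectrum100.intensities[0:n:2].copy(),
        sweep_time=half_time,
    )
    return narrow, wide


@dataclass
class RangeResult:
    """Per-spot results for one sub-sweep range."""

    label: str
    d_obs: np.ndarray  # MHz, NaN where the fit failed
    delta_t: np.ndarray  # K, deviation from the series mean
    sd_accuracy: Optional[AccuracyRecord]
    fit_error_accuracy_mean: Optional[float]  # K/Hz^1/2, mean over repeats
    n_nonconverged: int


@dataclass
class SpotReport:
    spot: SpotROI
    narrow: RangeResult
    wide: RangeResult
    winner: str  # "narrow" | "wide" | "tie"
    excluded: bool
    exclusion_reason: Optional[str] = None


@dataclass
class StackSummary:
    n_spots: int
    n_analyzed: int
    n_excluded: int
    fraction_narrow_wins: float
    n_narrow_wins: int
    n_wide_wins: int
    n_ties: int
    threshold_counts: dict  # {range label: {threshold K/Hz^1/2: count at or below}}


@dataclass(frozen=True)
class AnalyzeConfig:
    threshold_sigmas: float = 5.0
    roi_edge_um: float = 7.0
    min_separation_um: float = 7.0
    max_nonconverged_fraction: float = 0.20
    tie_epsilon: float = 1e-3  # K/Hz^1/2; accuracy gaps below this are ties
    accuracy_thresholds: tuple[float, ...] = (3.0, 2.0, 1.0)
    constants: ThermometryConstants = DEFAULT_CONSTANTS


def _analyze_range(
    label: str,
    spectra: list[Spectrum],
    config: AnalyzeConfig,
) -> RangeResult:
    """Fit one sub-sweep's repeat series with the vectorized fitter."""
    omega = spectra[0].frequencies
    data = np.stack([s.intensities for s in spectra])
    res = fitting.fit_replicates(omega, data)
    d_obs = np.where(res.converged, res.params[:, 0], np.nan)
    se_d = np.where(res.converged, res.std_errors[:, 0], np.nan)
    sweep_time = spectra[0].sweep_time
    n_bad = int((~res.converged).sum())

    finite = d_obs[np.isfinite(d_obs)]
    sd_acc = None
    if len(finite) >= 2:
        sd_acc = accuracy_from_series(
            d_obs, sweep_time, config.constants, source=label
        )
    mean_fit_err = None
    if np.isfinite(se_d).any():
        mean_fit_err = float(
            np.nanmean(se_d) / config.constants.dD_dT_magnitude * math.sqrt(sweep_time)
        )
    delta_t = np.full_like(d_obs, np.nan)
    if len(finite) > 0:
        mean_d = finite.mean()
        ok = np.isfinite(d_obs)
        delta_t[ok] = [
            d_shift_to_temperature_shift(d - mean_d, config.constants)
            for d in d_obs[ok]
        ]
    return RangeResult(
        label=label,
        d_obs=d_obs,
        delta_t=delta_t,
        sd_accuracy=sd_acc,
        fit_error_accuracy_mean=mean_fit_err,
        n_nonconverged=n_bad,
    )


def analyze_stack(
    stack: ImageStack, config: AnalyzeConfig = AnalyzeConfig()
) -> tuple[list[SpotReport], StackSummary]:
    """Full pipeline: detect spots, extract and decompose every repeat,
    fit both sub-sweeps, and tally per-spot accuracies and winners.

    Spots whose narrow or wide fit series exceeds the non-convergence budget
    are excluded from the summary but still reported (flagged).
    """
    if stack.n_repeats < 2:
        raise ValueError("need >= 2 sweep repeats to estimate accuracies")
    rois = detect_bright_spots(
        stack.mean_image(),
        stack.pixel_size_um,
        threshold_sigmas=config.threshold_sigmas,
        min_separation_um=config.min_separation_um,
        roi_edge_um=config.roi_edge_um,
    )
    reports: list[SpotReport] = []
    for roi in rois:
        narrow_specs, wide_specs = [], []
        for rep in range(stack.n_repeats):
            full = extract_spot_spectrum(stack, roi, rep)
            narrow, wide = decompose_sweep(full)
            narrow_specs.append(narrow)
            wide_specs.append(wide)
        narrow_res = _analyze_range("narrow", narrow_specs, config)
        wide_res = _analyze_range("wide", wide_specs, config)

        excluded = False
        reason = None
        budget = config.max_nonconverged_fraction * stack.n_repeats
        for res in (narrow_res, wide_res):
            if res.sd_accuracy is None:
                excluded, reason = True, f"{res.label}: too few converged fits"
            elif res.n_nonconverged > budget:
                excluded, reason = (
                    True,
                    f"{res.label}: {res.n_nonconverged}/{stack.n_repeats} fits failed",
                )
        if excluded:
            winner = "tie"
        else:
            gap = narrow_res.sd_accuracy.value - wide_res.sd_accuracy.value
            if abs(gap) <= config.tie_epsilon:
                winner = "tie"
            else:
                winner = "narrow" if gap < 0 else "wide"
        reports.append(
            SpotReport(
                spot=roi,
                narrow=narrow_res,
                wide=wide_res,
                winner=winner,
                excluded=excluded,
                exclusion_reason=reason,
            )
        )

    analyzed = [r for r in reports if not r.excluded]
    n_narrow = sum(1 for r in analyzed if r.winner == "narrow")
    n_wide = sum(1 for r in analyzed if r.winner == "wide")
    n_tie = sum(1 for r in analyzed if r.winner == "tie")
    decided = n_narrow + n_wide
    threshold_counts = {
        label: {
            thr: sum(
                1
                for r in analyzed
                if getattr(r, label).sd_accuracy.value <= thr
            )
            for thr in config.accuracy_thresholds
        }
        for label in ("narrow", "wide")
    }
    summary = StackSummary(
        n_spots=len(reports),
        n_analyzed=len(analyzed),
        n_excluded=len(reports) - len(analyzed),
        fraction_narrow_wins=(n_narrow / decided) if decided else float("nan"),
        n_narrow_wins=n_narrow,
        n_wide_wins=n_wide,
        n_ties=n_tie,
        threshold_counts=threshold_counts,
    )
    return reports, summary


def reports_to_csv(reports: list[SpotReport], path: Union[str, Path]) -> None:
    """Flat per-spot accuracy table: spot_id,range,method,accuracy_k_per_sqrthz."""
    lines = ["spot_id,range,method,accuracy_k_per_sqrthz"]
    for rep in reports:
        for res in (rep.narrow, rep.wide):
            if res.sd_accuracy is not None:
                lines.append(
                    f"{rep.spot.spot_id},{res.label},sd_of_repeats,"
                    f"{res.sd_accuracy.value!r}"
                )
            if res.fit_error_accuracy_mean is not None:
                lines.append(
                    f"{rep.spot.spot_id},{res.label},fit_error,"
                    f"{res.fit_error_accuracy_mean!r}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def summary_to_json(summary: StackSummary, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(summary), indent=1))
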