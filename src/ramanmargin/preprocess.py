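"""Spectral preprocessing chain for line-scan Raman cubes.

The chain mirrors standard practice for fiber-coupled dispersive Raman
imagers and is applied in this fixed order:

1. **Cosmic-ray removal** — running median filter over each spectrum.
2. **Raman-shift calibration** — a cubic spline through the six most
   prominent peaks of an acetaminophen reference measurement maps detector
   pixels to cm^-1 (acetaminophen is an ASTM E1840 shift standard).
3. **System-response correction** — division by a 2-D Gaussian-smoothed
   broadband intensity-standard measurement; spectra on the cube borders are
   rejected because the smoothing kernel is ill-supported there.
4. **Background removal** — fifth-order polynomial fit followed by a
   rolling-ball pass (ball radius 16 channels) on the residual.
5. **SNV normalization** — each spectrum to zero mean, unit sample
   standard deviation.

Pixels whose relative illumination falls below a threshold (40% by default)
are additionally masked out, mirroring the dark column visible at the
low-illumination end of the laser line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import PchipInterpolator

from .baseline import remove_baseline
from .containers import HyperspectralCube, Spectrum
from .errors import (
    CalibrationError,
    ConfigurationError,
    NormalizationError,
    NumericalError,
    ParameterError,
)
from .synthetic import ACETAMINOPHEN_PEAKS

__all__ = [
    "PreprocessConfig",
    "WavenumberCalibration",
    "ProcessedCube",
    "QCReport",
    "remove_cosmic_rays",
    "calibrate_wavenumber",
    "correct_system_response",
    "remove_background",
    "snv_normalize",
    "mask_low_illumination",
    "intensity_images",
    "preprocess_cube",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain (defaults as used here)."""

    median_window: int = 5
    n_calibration_peaks: int = 6
    calibration_peaks: tuple[float, ...] = ACETAMINOPHEN_PEAKS
    response_smooth_sigma: tuple[float, float] = (2.5, 2.5)  # (spatial, spectral) px
    border_width: int = 1
    poly_order: int = 5
    ball_size: int = 16
    illumination_threshold: float = 0.40

    def __post_init__(self) -> None:
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ConfigurationError("median_window must be odd and >= 3")
        if self.poly_order < 0:
            raise ConfigurationError("poly_order must be >= 0")
        if self.ball_size < 1:
            raise ConfigurationError("ball_size must be >= 1")
        if not 0.0 <= self.illumination_threshold <= 1.0 + 1e-9:
            # threshold > 1 is allowed only as an explicit mask-everything request
            if self.illumination_threshold < 0:
                raise ConfigurationError("illumination_threshold must be >= 0")
        if self.border_width < 0:
            raise ConfigurationError("border_width must be >= 0")


def remove_cosmic_rays(
    spectrum,
    median_window: int = 5,
    rel_threshold: float = 2.0,
    mad_factor: float = 8.0,
):
    """Median-filter based cosmic-ray elimination along the spectral axis.

    A running median (width ``median_window``, reflected edges) provides the
    local reference level; channels whose excess above it exceeds both
    ``mad_factor`` times the robust residual scale and ``rel_threshold``
    times the local reference are flagged as cosmic rays and replaced by
    linear interpolation across their unflagged neighbors.  Cosmic rays are
    one-to-few-channel excursions of 10-100x the local signal, far above
    both thresholds, while genuine Raman bands stay below them — so real
    lineshapes pass through untouched.

    Accepts a :class:`Spectrum` or an ndarray whose last axis is spectral;
    returns the same type.
    """
    if median_window % 2 == 0 or median_window < 3:
        raise ParameterError("median window must be odd and >= 3")
    if isinstance(spectrum, Spectrum):
        filtered = remove_cosmic_rays(
            spectrum.intensities, median_window, rel_threshold, mad_factor
        )
        return Spectrum(filtered, spectrum.axis.copy(), spectrum.axis_kind)
    arr = np.asarray(spectrum, dtype=float)
    n = arr.shape[-1]
    if median_window >= n:
        raise ParameterError("median window must be smaller than the spectrum")
    size = (1,) * (arr.ndim - 1) + (median_window,)
    med = ndimage.median_filter(arr, size=size, mode="reflect")
    resid = arr - med
    mad = np.median(np.abs(resid), axis=-1, keepdims=True)
    threshold = np.maximum(mad_factor * mad, rel_threshold * np.abs(med))
    spike = resid > threshold

    out = arr.copy()
    flat_out = out.reshape(-1, n)
    flat_spike = spike.reshape(-1, n)
    rows = np.flatnonzero(flat_spike.any(axis=-1))
    idx = np.arange(n)
    for r in rows:
        bad = flat_spike[r]
        good = ~bad
        if good.sum() < 2:
            continue
        flat_out[r, bad] = np.interp(idx[bad], idx[good], flat_out[r, good])
    return out


@dataclass
class WavenumberCalibration:
    """Monotone pixel -> cm^-1 mapping anchored at detected reference peaks."""

    knots: np.ndarray  # (n, 2) rows (detected pixel, reference shift)
    _spline: PchipInterpolator = field(repr=False)

    def __post_init__(self) -> None:
        if self.knots.shape[0] < 2:
            raise CalibrationError("calibration needs at least two knots")

    def __call__(self, pixels) -> np.ndarray:
        """Evaluate the mapping; linear extrapolation beyond the outer knots."""
        p = np.asarray(pixels, dtype=float)
        lo, hi = self.knots[0, 0], self.knots[-1, 0]
        out = self._spline(np.clip(p, lo, hi))
        dlo = float(self._spline.derivative()(lo))
        dhi = float(self._spline.derivative()(hi))
        out = np.where(p < lo, self._spline(lo) + dlo * (p - lo), out)
        out = np.where(p > hi, self._spline(hi) + dhi * (p - hi), out)
        return out


def _refine_peak(y: np.ndarray, idx: int) -> float:
    """Sub-pixel peak position by parabolic interpolation on log intensity."""
    if idx <= 0 or idx >= y.size - 1:
        return float(idx)
    triple = y[idx - 1 : idx + 2]
    if np.any(triple <= 0):
        a, b, c = triple
    else:
        a, b, c = np.log(triple)
    denom = a - 2 * b + c
    if denom >= 0:
        return float(idx)
    return float(idx + 0.5 * (a - c) / denom)


def calibrate_wavenumber(
    reference: Spectrum,
    peak_table: Sequence[float] = ACETAMINOPHEN_PEAKS,
    n_peaks: int = 6,
) -> WavenumberCalibration:
    """Fit the pixel -> cm^-1 mapping from a shift-standard measurement.

    The ``n_peaks`` most prominent maxima of the reference spectrum (minimum
    separation 3 channels, ties broken toward lower pixel index) are paired
    in pixel order with the sorted reference shifts, and a monotone cubic
    spline is fitted through the pairs.
    """
    if reference.axis_kind != "pixel":
        raise CalibrationError("calibration reference must be on the pixel axis")
    shifts = np.asarray(sorted(peak_table), dtype=float)
    if shifts.size < n_peaks:
        raise CalibrationError(
            f"peak table has {shifts.size} entries but {n_peaks} are required"
        )
    y = reference.intensities
    idx, props = signal.find_peaks(y, prominence=0.0, distance=3)
    if idx.size < n_peaks:
        raise CalibrationError(
            f"only {idx.size} peaks detectable; {n_peaks} required"
        )
    # prominence-ranked; stable sort keeps lower pixel index on ties
    order = np.argsort(-props["prominences"], kind="stable")
    top = np.sort(idx[order[:n_peaks]])
    detected = np.array([_refine_peak(y, int(i)) for i in top])
    refs = shifts[:n_peaks] if shifts.size == n_peaks else _match_shifts(shifts, n_peaks)
    knots = np.column_stack([detected, refs])
    if not (np.all(np.diff(knots[:, 0]) > 0) and np.all(np.diff(knots[:, 1]) > 0)):
        raise CalibrationError("knot sequence is not strictly monotone")
    spline = PchipInterpolator(knots[:, 0], knots[:, 1])
    return WavenumberCalibration(knots=knots, _spline=spline)


def _match_shifts(shifts: np.ndarray, n_peaks: int) -> np.ndarray:
    # when the table is larger than n_peaks, use the n_peaks entries in order;
    # the default table already contains exactly the six calibration bands
    return shifts[:n_peaks]


def correct_system_response(
    cube: HyperspectralCube,
    standard: np.ndarray,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[HyperspectralCube, np.ndarray]:
    """Divide out the smoothed intensity-standard measurement.

    ``standard`` has shape ``(n_y, n_channels)``; it is smoothed with a 2-D
    Gaussian (sigmas from the config) and normalized to unit mean before each
    ``(y, channel)`` plane of the cube is divided by it.  Returns the
    corrected cube and a boolean border-rejection mask of shape
    ``(n_lines, n_y)`` (True = rejected).
    """
    std = np.asarray(standard, dtype=float)
    if std.shape != (cube.n_y, cube.n_channels):
        raise ConfigurationError(
            f"standard shape {std.shape} does not match (n_y, n_channels) = "
            f"({cube.n_y}, {cube.n_channels})"
        )
    sy, sc = config.response_smooth_sigma
    smoothed = ndimage.gaussian_filter(std, sigma=(sy, sc), mode="nearest")
    if np.any(smoothed <= 0):
        bad = np.argwhere(smoothed <= 0)[0]
        raise NumericalError(
            f"smoothed standard non-positive at (y={bad[0]}, channel={bad[1]})"
        )
    smoothed = smoothed / smoothed.max()
    corrected = cube.data / smoothed[None, :, :]

    border = np.zeros((cube.n_lines, cube.n_y), dtype=bool)
    w = config.border_width
    if w > 0:
        border[:w, :] = True
        border[-w:, :] = True
        border[:, :w] = True
        border[:, -w:] = True
    out = HyperspectralCube(corrected, cube.axis.copy(), cube.axis_kind, dict(cube.metadata))
    out.metadata["border_mask"] = border
    return out, border


def remove_background(spectrum, poly_order: int = 5, ball_size: int = 16):
    """Polynomial + rolling-ball background removal.

    Accepts a :class:`Spectrum` (returns ``(signal, background)`` as
    Spectra) or an ndarray with spectral last axis (returns arrays).
    """
    if isinstance(spectrum, Spectrum):
        sig, bg = remove_baseline(spectrum.intensities, poly_order, ball_size)
        return (
            Spectrum(sig, spectrum.axis.copy(), spectrum.axis_kind),
            Spectrum(bg, spectrum.axis.copy(), spectrum.axis_kind),
        )
    return remove_baseline(np.asarray(spectrum, dtype=float), poly_order, ball_size)


def snv_normalize(spectrum):
    """Standard normal variate: per spectrum, subtract the mean and divide by
    the sample (n-1) standard deviation."""
    if isinstance(spectrum, Spectrum):
        out = snv_normalize(spectrum.intensities)
        return Spectrum(out, spectrum.axis.copy(), spectrum.axis_kind)
    arr = np.asarray(spectrum, dtype=float)
    sd = arr.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise NormalizationError("constant spectrum cannot be SNV-normalized")
    return (arr - arr.mean(axis=-1, keepdims=True)) / sd


def mask_low_illumination(
    cube: HyperspectralCube, illumination_map: np.ndarray, threshold: float = 0.40
) -> np.ndarray:
    """Boolean pixel mask (True = masked) where relative illumination < threshold.

    ``illumination_map`` may be per-pixel ``(n_lines, n_y)`` or per-line-
    position ``(n_y,)``; it is normalized to max 1 before comparison.
    """
    illum = np.asarray(illumination_map, dtype=float)
    if illum.ndim == 1:
        if illum.size != cube.n_y:
            raise ConfigurationError("1-D illumination map must have length n_y")
        illum = np.broadcast_to(illum, (cube.n_lines, cube.n_y))
    if illum.shape != (cube.n_lines, cube.n_y):
        raise ConfigurationError("illumination map shape mismatch")
    illum = illum / illum.max()
    return illum < threshold


def intensity_images(
    raw_cube: np.ndarray,
    background_cube: np.ndarray,
    signal_cube: np.ndarray,
    axis: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel trapezoidal integrals over the spectral axis.

    Returns the (raw luminescence, estimated background, Raman signal)
    intensity images; the background image is clipped at zero.
    """
    raw = np.asarray(raw_cube, dtype=float)
    bg = np.asarray(background_cube, dtype=float)
    sig = np.asarray(signal_cube, dtype=float)
    if not raw.shape == bg.shape == sig.shape:
        raise ConfigurationError("intensity_images requires cubes of equal shape")
    x = np.asarray(axis, dtype=float)
    lum_img = np.trapezoid(raw, x, axis=-1)
    bg_img = np.clip(np.trapezoid(bg, x, axis=-1), 0.0, None)
    sig_img = np.trapezoid(sig, x, axis=-1)
    return lum_img, bg_img, sig_img


@dataclass
class QCReport:
    """Bookkeeping of the preprocessing run."""

    n_total: int
    n_border_rejected: int
    n_low_illumination: int
    n_retained: int
    stage_stats: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_border_rejected": self.n_border_rejected,
            "n_low_illumination": self.n_low_illumination,
            "n_retained": self.n_retained,
            "stage_stats": dict(self.stage_stats),
        }


@dataclass
class ProcessedCube:
    """SNV-normalized cube plus retention mask and provenance."""

    data: np.ndarray  # (n_lines, n_y, n_channels) SNV spectra
    axis: np.ndarray  # calibrated wavenumber axis (cm^-1)
    retained: np.ndarray  # (n_lines, n_y) bool, True = usable spectrum
    background: np.ndarray  # estimated background cube (post-correction units)
    qc: QCReport
    metadata: dict = field(default_factory=dict)

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_y(self) -> int:
        return self.data.shape[1]


def preprocess_cube(
    cube: HyperspectralCube,
    calibration_reference: Spectrum | None,
    standard: np.ndarray | None,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[ProcessedCube, QCReport]:
    """Run the full preprocessing chain on a cube.

    ``calibration_reference`` may be ``None`` for cubes whose axis is already
    in wavenumbers; ``standard`` may be ``None`` to skip response correction
    (border rejection still applies).
    """
    data = remove_cosmic_rays(cube.data, config.median_window)
    working = HyperspectralCube(data, cube.axis.copy(), cube.axis_kind, dict(cube.metadata))

    if calibration_reference is not None:
        cal = calibrate_wavenumber(
            calibration_reference, config.calibration_peaks, config.n_calibration_peaks
        )
        axis = cal(np.arange(working.n_channels))
        working = HyperspectralCube(working.data, axis, "wavenumber", working.metadata)
    elif working.axis_kind != "wavenumber":
        raise CalibrationError(
            "cube axis is in pixels and no calibration reference was given"
        )

    if standard is not None:
        working, border = correct_system_response(working, standard, config)
    else:
        border = np.zeros((working.n_lines, working.n_y), dtype=bool)
        w = config.border_width
        if w > 0:
            border[:w, :] = True
            border[-w:, :] = True
            border[:, :w] = True
            border[:, -w:] = True

    illum = working.metadata.get("illumination")
    if illum is not None:
        low = mask_low_illumination(working, illum, config.illumination_threshold)
    else:
        low = np.zeros_like(border)

    flat = working.data.reshape(-1, working.n_channels)
    signal_flat, background_flat = remove_baseline(
        flat, config.poly_order, config.ball_size
    )
    snv_flat = snv_normalize(signal_flat)
    shape = working.data.shape
    snv_cube = snv_flat.reshape(shape)
    background_cube = background_flat.reshape(shape)

    retained = ~(border | low)
    qc = QCReport(
        n_total=working.n_spectra,
        n_border_rejected=int(border.sum()),
        n_low_illumination=int((low & ~border).sum()),
        n_retained=int(retained.sum()),
        stage_stats={
            "median_window": float(config.median_window),
            "mean_background_fraction": float(
                np.mean(background_flat.sum(axis=-1))
                / max(float(np.mean(flat.sum(axis=-1))), 1e-12)
            ),
        },
    )
    processed = ProcessedCube(
        data=snv_cube,
        axis=working.axis.copy(),
        retained=retained,
        background=background_cube,
        qc=qc,
        metadata=dict(working.metadata),
    )
    return processed, qc
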