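"""Acquisition-geometry arithmetic and the point-probe vs line-scanner
photon-budget comparison.

The photon budget is a multiplicative account of the factors by which a
single-point Raman probe out-collects the line scanner for the same
interrogated unit area and acquisition time: illumination intensity on the
sample, fiber-bundle transmission, collection-branch numerical aperture, and
the number (and effective fill) of collecting fibers.  The overall ratio is
the product of the four factors.

The NA factor is not derivable from the two NA values by a single obvious
formula (solid-angle scaling would give ``(NA_point / NA_line)**2``), so it
is accepted directly as a parameter, with the solid-angle formula available
as an opt-in alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ConfigurationError

__all__ = [
    "AcquisitionGeometry",
    "PhotonBudgetParams",
    "BudgetReport",
    "line_intensity",
    "fov_area",
    "total_exposure",
    "pixels_per_mm",
    "budget_ratios",
    "default_geometry",
    "default_budget_params",
    "upgraded_budget_params",
    "mw_to_w",
    "um_to_cm",
    "mm_to_cm",
]


def mw_to_w(mw: float) -> float:
    return mw * 1e-3


def um_to_cm(um: float) -> float:
    return um * 1e-4


def mm_to_cm(mm: float) -> float:
    return mm * 1e-1


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Line-scan acquisition geometry and laser parameters."""

    n_lines: int = 40
    line_step_um: float = 250.0
    line_length_mm: float = 9.5
    line_width_um: float = 400.0
    laser_power_mw: float = 230.0
    exposure_per_line_s: float = 5.0

    def __post_init__(self) -> None:
        vals = (
            self.n_lines,
            self.line_step_um,
            self.line_length_mm,
            self.line_width_um,
            self.laser_power_mw,
            self.exposure_per_line_s,
        )
        if any(v <= 0 for v in vals):
            raise ConfigurationError("all geometry parameters must be positive")


def default_geometry() -> AcquisitionGeometry:
    return AcquisitionGeometry()


def line_intensity(geometry: AcquisitionGeometry) -> float:
    """Mean laser intensity on the sample in W/cm^2 (power / line area)."""
    area_cm2 = um_to_cm(geometry.line_width_um) * mm_to_cm(geometry.line_length_mm)
    if area_cm2 == 0:
        raise ConfigurationError("line area is zero")
    return mw_to_w(geometry.laser_power_mw) / area_cm2


def fov_area(geometry: AcquisitionGeometry) -> float:
    """Scanned field of view in mm^2 (lines x step x length)."""
    return geometry.n_lines * geometry.line_step_um * 1e-3 * geometry.line_length_mm


def total_exposure(geometry: AcquisitionGeometry) -> float:
    """Total scan exposure in seconds."""
    return geometry.n_lines * geometry.exposure_per_line_s


def pixels_per_mm(geometry: AcquisitionGeometry) -> float:
    """Spatial sampling density along the scan axis."""
    return 1000.0 / geometry.line_step_um


@dataclass(frozen=True)
class PhotonBudgetParams:
    """Point-probe vs line-scanner instrument parameters.

    ``na_ratio`` is the collection-NA advantage factor taken as a direct
    input; set ``na_ratio=None`` to derive it as ``(na_point / na_line)**2``.
    """

    intensity_point: float = 38.2  # W/cm^2
    intensity_line: float = 6.1  # W/cm^2
    bundle_transmission: float = 0.375
    na_point: float = 0.22
    na_line: float = 0.159
    na_ratio: float | None = 1.96
    n_fibers_point: int = 7
    fiber_fill_point: float = 0.417

    def __post_init__(self) -> None:
        if self.intensity_point <= 0 or self.intensity_line <= 0:
            raise ConfigurationError("intensities must be > 0")
        if not 0 < self.bundle_transmission <= 1:
            raise ConfigurationError("bundle_transmission must be in (0, 1]")
        if not 0 < self.fiber_fill_point <= 1:
            raise ConfigurationError("fiber_fill_point must be in (0, 1]")
        if self.n_fibers_point < 1:
            raise ConfigurationError("n_fibers_point must be >= 1")


def default_budget_params() -> PhotonBudgetParams:
    return PhotonBudgetParams()


def upgraded_budget_params() -> PhotonBudgetParams:
    """What-if preset: 5 W fiber-coupled laser, NA 0.36, 400 um x 10 mm line."""
    geometry = AcquisitionGeometry(
        line_width_um=400.0, line_length_mm=10.0, laser_power_mw=5000.0
    )
    return replace(
        PhotonBudgetParams(),
        intensity_line=line_intensity(geometry),
        na_line=0.36,
        na_ratio=None,
    )


@dataclass(frozen=True)
class BudgetReport:
    """Per-factor ratios (point / line) and their product."""

    intensity_ratio: float
    transmission_ratio: float
    na_ratio: float
    fiber_ratio: float
    overall: float
    overall_from_rounded: float

    def rounded(self) -> dict[str, float]:
        return {
            "intensity_ratio": round(self.intensity_ratio, 1),
            "transmission_ratio": round(self.transmission_ratio, 2),
            "na_ratio": round(self.na_ratio, 2),
            "fiber_ratio": round(self.fiber_ratio, 2),
            "overall": round(self.overall),
        }


def budget_ratios(params: PhotonBudgetParams = PhotonBudgetParams()) -> BudgetReport:
    """Compute the per-factor and overall photon-budget ratios."""
    intensity_ratio = params.intensity_point / params.intensity_line
    transmission_ratio = 1.0 / params.bundle_transmission
    fiber_ratio = params.n_fibers_point * params.fiber_fill_point
    if params.na_ratio is not None:
        na_ratio = params.na_ratio
    else:
        na_ratio = (params.na_point / params.na_line) ** 2
    overall = intensity_ratio * transmission_ratio * na_ratio * fiber_ratio
    overall_rounded = (
        round(intensity_ratio, 1)
        * round(transmission_ratio, 2)
        * round(na_ratio, 2)
        * round(fiber_ratio, 2)
    )
    return BudgetReport(
        intensity_ratio=intensity_ratio,
        transmission_ratio=transmission_ratio,
        na_ratio=na_ratio,
        fiber_ratio=fiber_ratio,
        overall=overall,
        overall_from_rounded=overall_rounded,
    )
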