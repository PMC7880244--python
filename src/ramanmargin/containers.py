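"""Core in-memory containers shared across the pipeline.

A line-scan acquisition produces, for each laser-line position (the scan or
*x* axis), a full set of spectra along the line (the *y* axis), giving a
hyperspectral cube indexed ``(x, y, channel)``.  The spectral axis is either
raw detector pixels (before calibration) or Raman shifts in cm^-1 (after).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ConfigurationError

__all__ = ["Spectrum", "HyperspectralCube"]


@dataclass
class Spectrum:
    """A single spectrum with its spectral axis.

    Parameters
    ----------
    intensities : ndarray
        Measured intensities (arbitrary counts).
    axis : ndarray
        Per-element spectral coordinate, strictly increasing.  Raw detector
        pixel indices or Raman shifts (cm^-1) depending on ``axis_kind``.
    axis_kind : {"pixel", "wavenumber"}
    """

    intensities: np.ndarray
    axis: np.ndarray
    axis_kind: str = "pixel"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.intensities.ndim != 1:
            raise ConfigurationError("Spectrum intensities must be 1-D")
        if self.intensities.shape != self.axis.shape:
            raise ConfigurationError(
                f"axis length {self.axis.size} does not match "
                f"intensities length {self.intensities.size}"
            )
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ConfigurationError("spectral axis must be strictly increasing")
        if self.axis_kind not in ("pixel", "wavenumber"):
            raise ConfigurationError(f"unknown axis_kind {self.axis_kind!r}")

    def __len__(self) -> int:
        return self.intensities.size

    def copy(self) -> "Spectrum":
        return Spectrum(self.intensities.copy(), self.axis.copy(), self.axis_kind)


@dataclass
class HyperspectralCube:
    """Line-scanned hyperspectral cube, shape ``(n_lines, n_y, n_channels)``.

    ``metadata`` carries acquisition geometry (``line_step_um``,
    ``line_length_mm``, ``exposure_s``, ``seed``) plus optional per-pixel
    auxiliaries such as the relative-illumination map (``illumination``,
    shape ``(n_y,)`` normalized to max 1).
    """

    data: np.ndarray
    axis: np.ndarray
    axis_kind: str = "pixel"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("cube data must be 3-D (x, y, channel)")
        if self.data.shape[2] != self.axis.size:
            raise ConfigurationError(
                f"spectral axis length {self.axis.size} does not match "
                f"cube channel count {self.data.shape[2]}"
            )
        if self.axis_kind not in ("pixel", "wavenumber"):
            raise ConfigurationError(f"unknown axis_kind {self.axis_kind!r}")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_y(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_spectra(self) -> int:
        return self.n_lines * self.n_y

    def spectra(self) -> np.ndarray:
        """Flattened view ``(n_lines * n_y, n_channels)``, x-major order."""
        return self.data.reshape(-1, self.n_channels)

    def copy(self) -> "HyperspectralCube":
        return HyperspectralCube(
            self.data.copy(), self.axis.copy(), self.axis_kind, dict(self.metadata)
        )
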