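"""Synthetic line-scan Raman scenes with known ground truth.

Emulates a macroscopic line-scanning Raman imager pointed at a two-tissue
margin (porcine adipose against muscle).  Each tissue class is a sum of
Lorentzian/Gaussian bands at the positions tabulated for porcine tissue:
muscle carries the 1001 cm^-1 phenylalanine breathing mode, adipose carries
strong CH2 deformation (1442 cm^-1) and ester carbonyl (1739 cm^-1) bands
and lacks 1001 cm^-1 entirely.  On top of the Raman signal the generator
adds

* an intense, smooth fluorescence background (several times the strongest
  Raman band, so raw luminescence shows no tissue contrast),
* a multiplicative system response with optional localized "scratch"
  artifacts on the intensity standard,
* signal-proportional shot noise, with adipose enjoying a higher SNR than
  muscle,
* single-channel cosmic-ray spikes, and
* a one-sided exponential bleed of adipose signal into near-margin muscle
  pixels, emulating the spatially offset (in-depth) signal contribution
  observed when the scan line crosses the margin.

Every stochastic component is driven by the scene seed, and the full
decomposition (clean Raman, background, spike list, response, noise sigma)
is returned as :class:`GroundTruth` so that downstream stages can be tested
against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .containers import HyperspectralCube, Spectrum
from .errors import ConfigurationError

__all__ = [
    "BandSpec",
    "TissueTemplate",
    "SceneConfig",
    "GroundTruth",
    "IntensityStandard",
    "ACETAMINOPHEN_PEAKS",
    "ACETAMINOPHEN_MINOR_PEAKS",
    "muscle_template",
    "adipose_template",
    "default_scene_config",
    "template_spectrum",
    "fluorescence_background",
    "generate_scene",
    "generate_calibration_reference",
    "generate_intensity_standard",
]

# Acetaminophen Raman-shift standard (ASTM E1840 consensus values, cm^-1).
# The six most prominent fingerprint-region bands used for calibration by
# default, plus weaker bands used to dress the reference spectrum.
ACETAMINOPHEN_PEAKS: tuple[float, ...] = (651.6, 857.9, 1168.5, 1236.8, 1323.9, 1648.4)
ACETAMINOPHEN_MINOR_PEAKS: tuple[float, ...] = (710.8, 797.2, 968.7, 1105.5, 1278.5, 1371.5, 1561.5)


@dataclass(frozen=True)
class BandSpec:
    """One Raman band: center (cm^-1), FWHM (cm^-1), relative amplitude."""

    center: float
    width: float = 10.0
    amplitude: float = 1.0
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if not 400.0 <= self.center <= 1900.0:
            raise ConfigurationError(
                f"band center {self.center} outside the fingerprint region 400-1900"
            )
        if self.width <= 0:
            raise ConfigurationError("band width must be > 0")
        if self.amplitude < 0:
            raise ConfigurationError("band amplitude must be >= 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ConfigurationError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        x = np.asarray(wavenumbers, dtype=float)
        if self.shape == "lorentzian":
            gamma = self.width / 2.0
            return self.amplitude / (1.0 + ((x - self.center) / gamma) ** 2)
        return self.amplitude * np.exp(
            -4.0 * np.log(2.0) * ((x - self.center) / self.width) ** 2
        )


@dataclass(frozen=True)
class TissueTemplate:
    """Spectral template for one tissue class."""

    name: str
    bands: tuple[BandSpec, ...]
    background_scale: float = 1.0
    snr_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigurationError(f"template {self.name!r} has no bands")
        if self.background_scale <= 0:
            raise ConfigurationError("background_scale must be > 0")
        if self.snr_scale <= 0:
            raise ConfigurationError("snr_scale must be > 0")

    def spectrum(self, wavenumbers: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(wavenumbers, dtype=float))
        for band in self.bands:
            out += band.profile(wavenumbers)
        return out


# (center, muscle amplitude, adipose amplitude) for the porcine bands.
# Muscle expresses the protein bands (620, 824, 853, 1001, 1604); adipose
# the lipid bands (967, 1082, 1298, 1346, 1739) with 1442 at roughly twice
# the muscle intensity and the 1001 phenylalanine band absent.
_PORCINE_BANDS: tuple[tuple[float, float, float], ...] = (
    (620.0, 0.30, 0.00),
    (824.0, 0.22, 0.00),
    (853.0, 0.35, 0.00),
    (886.0, 0.30, 0.45),
    (967.0, 0.08, 0.60),
    (1001.0, 1.00, 0.00),
    (1063.0, 0.30, 0.60),
    (1082.0, 0.20, 0.65),
    (1126.0, 0.30, 0.50),
    (1264.0, 0.35, 0.50),
    (1298.0, 0.25, 0.90),
    (1346.0, 0.35, 0.30),
    (1442.0, 1.00, 2.20),
    (1604.0, 0.35, 0.00),
    (1657.0, 0.70, 0.70),
    (1739.0, 0.00, 1.10),
)


def muscle_template(width: float = 10.0) -> TissueTemplate:
    bands = tuple(
        BandSpec(center=c, width=width, amplitude=a)
        for c, a, _ in _PORCINE_BANDS
        if a > 0
    )
    return TissueTemplate(name="muscle", bands=bands, snr_scale=1.0)


def adipose_template(width: float = 10.0) -> TissueTemplate:
    # adipose is the stronger Raman scatterer: higher snr_scale
    bands = tuple(
        BandSpec(center=c, width=width, amplitude=a)
        for c, _, a in _PORCINE_BANDS
        if a > 0
    )
    return TissueTemplate(name="adipose", bands=bands, snr_scale=1.6)


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic line-scan acquisition.

    The defaults reproduce the instrument geometry used throughout: 40 scan
    lines of 42 binned spatial pixels and 341 spectral channels covering
    400-1900 cm^-1, 250 um line step, 9.5 mm line length, 5 s exposure per
    line.  ``margin_column`` places the class boundary on the scan (x) axis:
    columns left of it belong to ``templates[0]``, the rest to
    ``templates[1]``; ``None`` gives a pure single-class scene of
    ``templates[0]``.
    """

    n_lines: int = 40
    n_y: int = 42
    n_channels: int = 341
    wavenumber_range: tuple[float, float] = (400.0, 1900.0)
    line_step_um: float = 250.0
    line_length_mm: float = 9.5
    exposure_s: float = 5.0
    margin_column: int | None = None
    bleed_length: float = 1.5
    bleed_amplitude: float = 0.35
    spike_rate: float = 0.01
    noise_scale: float = 1.0
    counts_scale: float = 200.0
    background_amplitude: float = 5.0
    seed: int = 0
    templates: tuple[TissueTemplate, TissueTemplate] = field(
        default_factory=lambda: (adipose_template(), muscle_template())
    )
    n_frames: int = 1
    apply_response: bool = True
    scratch_count: int = 3
    illumination_profile: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.n_lines, self.n_y, self.n_channels) < 1:
            raise ConfigurationError("cube dimensions must be >= 1")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ConfigurationError("spike_rate must lie in [0, 1]")
        if self.bleed_length < 0:
            raise ConfigurationError("bleed_length must be >= 0")
        if self.margin_column is not None and not 0 <= self.margin_column < self.n_lines:
            raise ConfigurationError(
                f"margin_column {self.margin_column} outside [0, {self.n_lines})"
            )
        if self.wavenumber_range[0] >= self.wavenumber_range[1]:
            raise ConfigurationError("wavenumber_range must be (min, max) with min < max")
        if len(self.templates) != 2:
            raise ConfigurationError("a scene requires exactly two templates")
        if self.templates[0].name == self.templates[1].name:
            raise ConfigurationError("scene templates must have distinct names")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")

    @property
    def wavenumbers(self) -> np.ndarray:
        lo, hi = self.wavenumber_range
        return np.linspace(lo, hi, self.n_channels)

    def with_seed(self, seed: int) -> "SceneConfig":
        return replace(self, seed=seed)


def default_scene_config(**overrides) -> SceneConfig:
    """The standard two-tissue margin scene with the boundary mid-FOV."""
    params = dict(margin_column=20)
    params.update(overrides)
    return SceneConfig(**params)


@dataclass
class GroundTruth:
    """Planted decomposition of a generated scene (the test oracle)."""

    label_map: np.ndarray  # (n_lines, n_y) of class-name strings
    clean_cube: np.ndarray  # noiseless, background-free Raman component
    background_cube: np.ndarray  # additive fluorescence component
    spike_list: np.ndarray  # (n_spikes, 3) int rows (x, y, channel)
    spike_amplitudes: np.ndarray  # (n_spikes,) added counts
    true_calibration: np.ndarray  # planted pixel -> cm^-1 axis
    noise_sigma: np.ndarray  # per-element noise std of the averaged cube
    response: np.ndarray  # (n_y, n_channels) smooth system response
    illumination: np.ndarray  # (n_y,) relative illumination, max 1


@dataclass
class IntensityStandard:
    """Simulated broadband intensity-standard measurement."""

    image: np.ndarray  # measured standard (n_y, n_channels), scratches included
    smooth: np.ndarray  # scratch-free component
    scratch_positions: np.ndarray  # (n, 2) int rows (y, channel)
    scratch_depths: np.ndarray  # (n,) relative depth in (0, 1)


def template_spectrum(template: TissueTemplate, wavenumbers: np.ndarray) -> np.ndarray:
    """Noise-free Raman spectrum of a template on the given axis (counts=1 scale)."""
    return template.spectrum(wavenumbers)


# fixed smooth shape for tissue autofluorescence: intense at low Raman shift,
# slowly decaying across the fingerprint region
_BACKGROUND_COEFFS = (1.0, -0.75, 0.45, -0.35, 0.25, -0.12)


def fluorescence_background(wavenumbers: np.ndarray) -> np.ndarray:
    """Unit-peak smooth fluorescence profile over the spectral axis."""
    lo, hi = float(wavenumbers[0]), float(wavenumbers[-1])
    u = (np.asarray(wavenumbers, dtype=float) - lo) / (hi - lo)
    prof = np.polynomial.polynomial.polyval(u, _BACKGROUND_COEFFS)
    if np.any(prof <= 0):
        raise ConfigurationError("background profile must be strictly positive")
    return prof / prof.max()


def _smooth_response(n_y: int, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative system response: spectral roll-off x spatial vignette."""
    u = np.linspace(0.0, 1.0, n_channels)
    c = np.array([1.0, 0.15, -0.35]) + rng.normal(0.0, 0.02, size=3)
    spectral = np.polynomial.polynomial.polyval(u, c)
    v = np.linspace(-1.0, 1.0, n_y)
    vignette = 1.0 - (0.10 + 0.05 * rng.random()) * v**2
    resp = np.outer(vignette, spectral)
    return resp / resp.max()


def _illumination(config: SceneConfig) -> np.ndarray:
    if config.illumination_profile is not None:
        prof = np.asarray(config.illumination_profile, dtype=float)
        if prof.size != config.n_y:
            raise ConfigurationError("illumination_profile length must equal n_y")
        return prof / prof.max()
    v = np.linspace(-1.0, 1.0, config.n_y)
    return 1.0 - 0.08 * v**2


def generate_scene(config: SceneConfig) -> tuple[HyperspectralCube, GroundTruth]:
    """Simulate one line-scan acquisition; returns the cube and its ground truth.

    The cube satisfies ``cube = clean + background + noise + spikes``
    element-wise, where the noise field is zero-mean Gaussian with standard
    deviation ``noise_scale * sqrt(clean + background) / snr_scale /
    sqrt(n_frames)`` (shot-noise approximation, reduced by frame averaging)
    and the clean component already includes the system response,
    illumination and cross-margin bleed.
    """
    wn = config.wavenumbers
    ss = np.random.SeedSequence(config.seed)
    rng_resp, rng_noise, rng_spike = (np.random.default_rng(s) for s in ss.spawn(3))

    left, right = config.templates
    label_map = np.empty((config.n_lines, config.n_y), dtype=object)
    if config.margin_column is None:
        label_map[:, :] = left.name
    else:
        label_map[: config.margin_column, :] = left.name
        label_map[config.margin_column :, :] = right.name
    label_map = label_map.astype(str)

    spec_by_name = {t.name: t.spectrum(wn) * config.counts_scale for t in (left, right)}
    max_amp = max(max(b.amplitude for b in t.bands) for t in (left, right))
    bg_profile = fluorescence_background(wn) * config.background_amplitude * max_amp * config.counts_scale
    bg_by_name = {t.name: bg_profile * t.background_scale for t in (left, right)}
    snr_by_name = {t.name: t.snr_scale for t in (left, right)}

    clean = np.zeros((config.n_lines, config.n_y, config.n_channels))
    background = np.zeros_like(clean)
    snr = np.ones((config.n_lines, config.n_y))
    for name in (left.name, right.name):
        sel = label_map == name
        clean[sel] = spec_by_name[name]
        background[sel] = bg_by_name[name]
        snr[sel] = snr_by_name[name]

    # asymmetric cross-margin bleed: the adipose (strong-scatterer) signal
    # leaks into near-margin pixels of the other class, one-sided in x
    if config.margin_column is not None and config.bleed_length > 0 and config.bleed_amplitude > 0:
        names = (left.name, right.name)
        if "adipose" in names:
            source = "adipose"
        else:
            source = left.name
        target = names[1] if source == names[0] else names[0]
        source_spec = spec_by_name[source]
        m = config.margin_column
        if source == left.name:
            cols = range(m, config.n_lines)
            dist = lambda x: x - m  # noqa: E731
        else:
            cols = range(0, m)
            dist = lambda x: (m - 1) - x  # noqa: E731
        for x in cols:
            if label_map[x, 0] != target:
                continue
            frac = config.bleed_amplitude * np.exp(-dist(x) / config.bleed_length)
            if frac < 1e-6:
                continue
            clean[x] += frac * source_spec

    illum = _illumination(config)
    resp = _smooth_response(config.n_y, config.n_channels, rng_resp)
    if not config.apply_response:
        resp = np.ones_like(resp)
    gain = resp[None, :, :] * illum[None, :, None]
    clean = clean * gain
    background = background * gain

    sigma = (
        config.noise_scale
        * np.sqrt(np.clip(clean + background, 0.0, None))
        / snr[:, :, None]
    )
    if config.noise_scale > 0:
        frames = rng_noise.normal(
            0.0, 1.0, size=(config.n_frames,) + clean.shape
        )
        noise = sigma[None] * frames
        noise = noise.mean(axis=0)
    else:
        noise = np.zeros_like(clean)
    sigma_avg = sigma / np.sqrt(config.n_frames)

    cube_data = clean + background + noise

    # cosmic rays: at most one single-channel positive spike per spectrum
    spikes: list[tuple[int, int, int]] = []
    amps: list[float] = []
    if config.spike_rate > 0:
        hit = rng_spike.random((config.n_lines, config.n_y)) < config.spike_rate
        xs, ys = np.nonzero(hit)
        chans = rng_spike.integers(0, config.n_channels, size=xs.size)
        factors = rng_spike.uniform(10.0, 100.0, size=xs.size)
        for x, y, ch, f in zip(xs, ys, chans, factors):
            amp = f * max(cube_data[x, y, ch], 1.0)
            cube_data[x, y, ch] += amp
            spikes.append((int(x), int(y), int(ch)))
            amps.append(float(amp))

    metadata = {
        "line_step_um": config.line_step_um,
        "line_length_mm": config.line_length_mm,
        "exposure_s": config.exposure_s,
        "seed": config.seed,
        "n_frames": config.n_frames,
        "illumination": illum,
    }
    cube = HyperspectralCube(
        data=cube_data,
        axis=np.arange(config.n_channels, dtype=float),
        axis_kind="pixel",
        metadata=metadata,
    )
    truth = GroundTruth(
        label_map=label_map,
        clean_cube=clean,
        background_cube=background,
        spike_list=np.array(spikes, dtype=int).reshape(-1, 3),
        spike_amplitudes=np.array(amps, dtype=float),
        true_calibration=wn.copy(),
        noise_sigma=sigma_avg,
        response=resp,
        illumination=illum,
    )
    return cube, truth


def _invert_calibration(
    true_calibration: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    n_channels: int,
    shifts: np.ndarray,
) -> np.ndarray:
    """Pixel positions whose image under the planted map is ``shifts``."""
    pixels = np.arange(n_channels, dtype=float)
    if callable(true_calibration):
        wn = np.asarray(true_calibration(pixels), dtype=float)
    else:
        wn = np.asarray(true_calibration, dtype=float)
        if wn.size != n_channels:
            raise ConfigurationError("true_calibration length must equal n_channels")
    if not np.all(np.diff(wn) > 0):
        raise ConfigurationError("true_calibration must be strictly increasing")
    return np.interp(shifts, wn, pixels)


def generate_calibration_reference(
    n_channels: int,
    true_calibration: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    peak_table: Sequence[float] = ACETAMINOPHEN_PEAKS,
    peak_width_px: float = 2.5,
    amplitude: float = 100.0,
) -> Spectrum:
    """Simulated acetaminophen reference measurement on the pixel axis.

    Gaussian peaks are planted at the pixel positions that the planted
    ``true_calibration`` maps onto each entry of ``peak_table``, at amplitude
    ``amplitude``; a few weaker bands (<= amplitude / 5) and a faint flat
    background dress the spectrum so peak-prominence ranking is exercised.
    """
    shifts = np.asarray(sorted(peak_table), dtype=float)
    pixels = np.arange(n_channels, dtype=float)
    if callable(true_calibration):
        wn = np.asarray(true_calibration(pixels), dtype=float)
    else:
        wn = np.asarray(true_calibration, dtype=float)
    in_range = (shifts >= wn[0]) & (shifts <= wn[-1])
    if int(in_range.sum()) < 6:
        raise ConfigurationError(
            "calibration requires at least 6 reference peaks inside the spectral range"
        )
    shifts = shifts[in_range]
    centers = _invert_calibration(true_calibration, n_channels, shifts)

    y = np.full(n_channels, 0.5)
    # slight amplitude spread keeps the prominence ranking unambiguous
    main_amps = amplitude * (1.0 + 0.05 * np.cos(np.arange(shifts.size)))
    for c, a in zip(centers, main_amps):
        y += a * np.exp(-0.5 * ((pixels - c) / peak_width_px) ** 2)
    minor = [s for s in ACETAMINOPHEN_MINOR_PEAKS if wn[0] < s < wn[-1]]
    minor_centers = _invert_calibration(true_calibration, n_channels, np.asarray(minor))
    for c in minor_centers:
        y += (amplitude / 8.0) * np.exp(-0.5 * ((pixels - c) / peak_width_px) ** 2)
    return Spectrum(intensities=y, axis=pixels, axis_kind="pixel")


def generate_intensity_standard(
    n_y: int,
    n_channels: int,
    scratch_count: int = 3,
    seed: int = 0,
    smooth: np.ndarray | None = None,
) -> IntensityStandard:
    """Simulated broadband (NIST-style) intensity-standard measurement.

    The scratch-free component is the smooth instrument response (slowly
    varying polynomial spectrally, mild vignetting spatially); scratches on
    the standard appear as localized multiplicative dips of 12-50% depth and
    at most 3 pixels width.
    """
    if n_y < 1 or n_channels < 1:
        raise ConfigurationError("standard dimensions must be >= 1")
    if scratch_count < 0:
        raise ConfigurationError("scratch_count must be >= 0")
    rng = np.random.default_rng(seed)
    if smooth is None:
        smooth = _smooth_response(n_y, n_channels, rng)
    else:
        smooth = np.asarray(smooth, dtype=float)
        if smooth.shape != (n_y, n_channels):
            raise ConfigurationError("smooth response shape must be (n_y, n_channels)")
    image = smooth.copy()

    yy, cc = np.meshgrid(np.arange(n_y), np.arange(n_channels), indexing="ij")
    positions: list[tuple[int, int]] = []
    depths: list[float] = []
    attempts = 0
    while len(positions) < scratch_count and attempts < 1000:
        attempts += 1
        y0 = int(rng.integers(2, max(3, n_y - 2)))
        c0 = int(rng.integers(2, max(3, n_channels - 2)))
        if any(abs(y0 - py) + abs(c0 - pc) < 8 for py, pc in positions):
            continue
        depth = float(rng.uniform(0.12, 0.50))
        dip = depth * np.exp(-(((yy - y0) ** 2 + (cc - c0) ** 2) / (2 * 0.8**2)))
        image *= 1.0 - dip
        positions.append((y0, c0))
        depths.append(depth)
    if len(positions) < scratch_count:
        raise ConfigurationError("could not place the requested number of scratches")
    return IntensityStandard(
        image=image,
        smooth=smooth,
        scratch_positions=np.array(positions, dtype=int).reshape(-1, 2),
        scratch_depths=np.array(depths, dtype=float),
    )
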