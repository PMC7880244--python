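"""Baseline estimation: polynomial fit followed by a rolling-ball pass.

The fluorescence background under a tissue Raman spectrum is orders of
magnitude more intense than the Raman bands themselves and varies smoothly
with wavenumber.  It is estimated in two stages:

1. a least-squares polynomial fit (order 5 by default) captures the bulk of
   the smooth fluorescence;
2. the residual baseline left by the fit is removed with a *rolling ball*:
   the background is the surface traced by a ball of a given radius rolled
   beneath the residual curve, i.e. a grayscale morphological opening with a
   spherical (non-flat) structuring element.

The ball radius is expressed in spectral channels; the ball height is scaled
to the interquartile range of the residual so that the ball geometry is
meaningful regardless of the intensity units.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

__all__ = [
    "ball_element",
    "grey_opening",
    "rolling_ball_background",
    "polynomial_baseline",
    "remove_baseline",
]


def ball_element(radius: int, height: float) -> np.ndarray:
    """Heights of a spherical structuring element of the given channel radius.

    Returns an array ``b`` of length ``2 * radius + 1`` with ``b[radius] = 0``
    at the apex and ``b = -height`` at the rims, tracing the upper half of an
    ellipse of semi-axes (radius, height).
    """
    if radius < 1:
        raise ParameterError("ball radius must be >= 1")
    if height < 0:
        raise ParameterError("ball height must be >= 0")
    k = np.arange(-radius, radius + 1, dtype=float)
    return height * (np.sqrt(1.0 - (k / radius) ** 2) - 1.0)


def grey_opening(y: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Grayscale opening (erosion then dilation) along the last axis.

    Window positions that extend past the signal boundaries are clipped: the
    minimum/maximum is taken over in-range samples only, so no padding value
    ever enters the result.
    """
    y = np.asarray(y, dtype=float)
    element = np.asarray(element, dtype=float)
    m = element.shape[-1]
    if m % 2 != 1:
        raise ParameterError("structuring element must have odd length")
    r = m // 2
    n = y.shape[-1]
    if n < 1:
        raise ParameterError("empty signal")

    def _b(k):
        # element may be one profile or one profile per spectrum
        return element[k] if element.ndim == 1 else element[..., k : k + 1]

    # erosion: e[j] = min_k (y[j + k] - b[k]); pad with +inf so clipped
    # positions never win the minimum
    pad = [(0, 0)] * (y.ndim - 1) + [(r, r)]
    yp = np.pad(y, pad, mode="constant", constant_values=np.inf)
    eroded = np.full_like(y, np.inf)
    for k in range(m):
        np.minimum(eroded, yp[..., k : k + n] - _b(k), out=eroded)

    # dilation: o[i] = max_k (e[i - k] + b[k]); pad with -inf
    ep = np.pad(eroded, pad, mode="constant", constant_values=-np.inf)
    opened = np.full_like(y, -np.inf)
    for k in range(m):
        np.maximum(opened, ep[..., (m - 1 - k) : (m - 1 - k) + n] + _b(k), out=opened)
    return opened


def rolling_ball_background(
    y: np.ndarray, radius: int = 16, height: float | None = None
) -> np.ndarray:
    """Rolling-ball background of ``y`` along the last axis.

    Parameters
    ----------
    y : ndarray
        Signal(s); the last axis is spectral.
    radius : int
        Ball radius in channels.
    height : float, optional
        Ball height in intensity units.  By default the interquartile range
        of ``y`` (per spectrum), which makes the ball shape commensurate with
        the data; ``height=0`` degenerates to a flat (min-max) filter.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[-1]
    if n < 2 * radius:
        raise ParameterError(
            f"signal length {n} shorter than twice the ball radius {radius}"
        )
    if height is None:
        q75, q25 = np.percentile(y, [75, 25], axis=-1)
        h = q75 - q25  # per-spectrum height
    else:
        h = np.asarray(height, dtype=float)
    shape = ball_element(radius, 1.0)
    element = np.asarray(h)[..., None] * shape if np.ndim(h) > 0 else ball_element(radius, float(h))
    return grey_opening(y, element)


def polynomial_baseline(y: np.ndarray, order: int = 5, n_iter: int = 5) -> np.ndarray:
    """Least-squares polynomial baseline along the last axis.

    Uses the standard iterated clipped fit: after each least-squares fit the
    data are clipped to ``min(y, fit)`` and refitted, so the polynomial
    settles under the peaks instead of being pulled up by them.  A single
    iteration (``n_iter=1``) is the plain least-squares fit.
    """
    y = np.asarray(y, dtype=float)
    if order < 0:
        raise ParameterError("polynomial order must be >= 0")
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    n = y.shape[-1]
    if n <= order:
        raise ParameterError("spectrum shorter than polynomial order + 1")
    u = np.linspace(-1.0, 1.0, n)
    flat = y.reshape(-1, n)
    work = flat
    for _ in range(n_iter):
        coeffs = np.polynomial.polynomial.polyfit(u, work.T, order)
        fitted = np.polynomial.polynomial.polyval(u, coeffs)
        if fitted.ndim == 1:
            fitted = fitted[None, :]
        work = np.minimum(work, fitted)
    return fitted.reshape(y.shape)


def remove_baseline(
    y: np.ndarray, poly_order: int = 5, ball_size: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage background removal; returns ``(signal, background)``.

    ``background`` is the order-``poly_order`` least-squares fit plus the
    rolling-ball opening (radius ``ball_size`` channels) of the fit residual;
    ``signal = y - background``.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] < 2 * ball_size:
        raise ParameterError(
            f"spectrum length {y.shape[-1]} shorter than 2 x ball_size {ball_size}"
        )
    poly = polynomial_baseline(y, poly_order)
    residual = y - poly
    ball = rolling_ball_background(residual, radius=ball_size)
    background = poly + ball
    return y - background, background
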