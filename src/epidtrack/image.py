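"""Core image container and the forward degradation model.

A megavoltage portal image is modeled as the observation ``g = H f + eta``:
the ideal scene ``f`` convolved with the detector point-spread function ``H``
plus additive noise ``eta``.  The PSF of the flat-panel imager is well
described by a normalized Lorentzian raised to the 3/2 power,

    h(x, y) = (1 + (x^2 + y^2) / lambda^2)^(-3/2)

with a single width parameter ``lambda`` in millimetres (a representative
value for a 6 MV beam is 0.5 mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError

__all__ = ["GrayImage", "PSFModel", "lorentzian_psf", "degrade_image"]


@dataclass(frozen=True)
class GrayImage:
    """A 2D grayscale image with isotropic pixel spacing.

    Intensities are finite, non-negative reals in arbitrary linear units
    (detector counts).  Row 0 is the top of the image; coordinates are
    (row, col), 0-based, with pixel centers at integer positions.
    """

    pixels: np.ndarray
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise InvalidParameterError("image must be 2D")
        if not np.all(np.isfinite(px)):
            raise InvalidParameterError("image intensities must be finite")
        if px.min() < 0:
            raise InvalidParameterError("image intensities must be non-negative")
        if not (self.pixel_spacing_mm > 0):
            raise InvalidParameterError("pixel_spacing_mm must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Same geometry, new intensities."""
        return GrayImage(pixels, self.pixel_spacing_mm)


@dataclass(frozen=True)
class PSFModel:
    """Discretized, normalized point-spread function.

    ``kernel`` sums to one and is symmetric under reflection of either axis;
    ``lam`` is the Lorentzian width parameter in mm.
    """

    lam: float
    kernel: np.ndarray
    support_half_width_px: int

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 2 or k.shape[0] != k.shape[1] or k.shape[0] % 2 != 1:
            raise InvalidParameterError("kernel must be square with odd side")
        if np.any(k < 0):
            raise InvalidParameterError("kernel entries must be non-negative")
        object.__setattr__(self, "kernel", k)


def default_support_half_width(lam: float, pixel_spacing_mm: float) -> int:
    """Default kernel support half-width in pixels: ceil(6 lambda / spacing)."""
    return int(np.ceil(6.0 * lam / pixel_spacing_mm))


def lorentzian_psf(
    lam: float,
    support_half_width_px: int | None = None,
    pixel_spacing_mm: float = 0.784,
) -> PSFModel:
    """Sample the Lorentzian^{3/2} PSF on a pixel grid and normalize it.

    The continuous form ``(1 + r^2/lambda^2)^(-3/2)`` is evaluated at pixel
    centers (in mm) within ``support_half_width_px`` pixels of the origin and
    renormalized to unit sum.  The radial tail of this profile is heavy
    (mass outside radius R falls off only like lambda/R), so a truncation
    check against the analytic mass is performed and a warning emitted when
    more than 1% of the continuous mass within reach is cut off.
    """
    if not (lam > 0):
        raise InvalidParameterError("lam must be > 0")
    if not (pixel_spacing_mm > 0):
        raise InvalidParameterError("pixel_spacing_mm must be > 0")
    if support_half_width_px is None:
        support_half_width_px = default_support_half_width(lam, pixel_spacing_mm)
    if support_half_width_px < 1:
        raise InvalidParameterError("support_half_width_px must be >= 1")

    hw = int(support_half_width_px)
    xs = np.arange(-hw, hw + 1) * pixel_spacing_mm
    X, Y = np.meshgrid(xs, xs)
    kernel = (1.0 + (X**2 + Y**2) / lam**2) ** -1.5

    # analytic 2D mass: total = 2 pi lam^2; within radius R:
    # 2 pi lam^2 (1 - (1 + R^2/lam^2)^(-1/2))
    R = hw * pixel_spacing_mm
    inside = 1.0 - (1.0 + R**2 / lam**2) ** -0.5
    truncated_over_inside = (1.0 - inside) / inside
    if truncated_over_inside > 0.01:
        warnings.warn(
            f"PSF support half-width {hw} px truncates "
            f"{100 * truncated_over_inside:.1f}% of the continuous Lorentzian "
            "mass relative to the retained part; consider a larger support",
            UserWarning,
            stacklevel=2,
        )

    kernel /= kernel.sum()
    return PSFModel(lam=lam, kernel=kernel, support_half_width_px=hw)


def degrade_image(
    ideal: GrayImage,
    psf: PSFModel,
    noise_sd: float,
    seed: int,
    quantize: bool = False,
) -> GrayImage:
    """Apply the forward model g = H f + eta.

    Convolution uses symmetric (mirror) boundary padding so that flat regions
    stay flat up to the image border.  ``eta`` is zero-mean Gaussian with the
    given standard deviation; negative results are clipped to zero.  With
    ``quantize`` the result is rounded to integer counts, as a real detector
    would report.  Bit-exact reproducible for a fixed seed.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    k = psf.kernel
    if k.shape[0] > ideal.shape[0] or k.shape[1] > ideal.shape[1]:
        raise InvalidParameterError("PSF kernel larger than image")
    if k.size == 1:
        blurred = ideal.pixels * k[0, 0]
    else:
        blurred = ndimage.convolve(ideal.pixels, k, mode="reflect")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        blurred = blurred + rng.normal(0.0, noise_sd, blurred.shape)
    out = np.clip(blurred, 0.0, None)
    if quantize:
        out = np.rint(out)
    return GrayImage(out, ideal.pixel_spacing_mm)
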