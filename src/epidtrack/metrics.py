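"""Image-quality measures: contrast, SNR, and edge-spread blurriness.

Contrast is (Iw - Ib)/Iw and SNR is Iw/sigma_b, where Iw and Ib are mean
intensities inside a white and a black reference box and sigma_b is the
sample standard deviation inside the black box.  Blurriness is the 10-90%
width of a sigmoid (Boltzmann/logistic) fit to an intensity profile drawn
across a tilted edge; for the logistic

    y = a_low + (a_high - a_low) / (1 + exp(-(x - x0)/dx))

the 10-90% width has the closed form 2*dx*ln(9).  All three measures are
reported both raw and normalized to a designated "original" arm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, optimize, special

from .errors import (
    DegenerateRegionError,
    FitFailureError,
    InvalidParameterError,
    NonEdgeProfileError,
)
from .image import GrayImage

__all__ = [
    "MetricBoxes",
    "EdgeProfileFit",
    "QualityReport",
    "contrast_metric",
    "snr_metric",
    "extract_profile",
    "fit_boltzmann",
    "blurriness_metric",
    "normalize_reports",
    "profile_minmax_match",
]

LN9 = float(np.log(9.0))


@dataclass(frozen=True)
class MetricBoxes:
    """White and black measurement rectangles, (row0, col0, row1, col1), half-open."""

    white_box: tuple[int, int, int, int]
    black_box: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for box in (self.white_box, self.black_box):
            r0, c0, r1, c1 = box
            if r1 - r0 < 10 or c1 - c0 < 10:
                raise InvalidParameterError("metric boxes must be at least 10x10")
        wr0, wc0, wr1, wc1 = self.white_box
        br0, bc0, br1, bc1 = self.black_box
        if not (wr1 <= br0 or br1 <= wr0 or wc1 <= bc0 or bc1 <= wc0):
            raise InvalidParameterError("metric boxes must be disjoint")


def _box_pixels(image: GrayImage, box: tuple[int, int, int, int]) -> np.ndarray:
    r0, c0, r1, c1 = box
    h, w = image.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise InvalidParameterError(f"box {box} outside image bounds {image.shape}")
    return image.pixels[r0:r1, c0:c1]


def contrast_metric(image: GrayImage, boxes: MetricBoxes) -> float:
    """(Iw - Ib) / Iw over the white/black boxes."""
    iw = float(_box_pixels(image, boxes.white_box).mean())
    ib = float(_box_pixels(image, boxes.black_box).mean())
    if iw <= 0:
        raise DegenerateRegionError("white box mean must be > 0")
    return (iw - ib) / iw


def snr_metric(image: GrayImage, boxes: MetricBoxes) -> float:
    """Iw / sigma_b with the sample (n-1) standard deviation of the black box."""
    iw = float(_box_pixels(image, boxes.white_box).mean())
    sb = float(_box_pixels(image, boxes.black_box).std(ddof=1))
    if sb == 0:
        raise DegenerateRegionError("black box has zero variance")
    return iw / sb


def extract_profile(
    image: GrayImage,
    p0: tuple[float, float],
    p1: tuple[float, float],
    n_samples: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinearly interpolated intensity profile along the segment p0 -> p1.

    Positions are arc length along the line in pixel units (an oblique line's
    sample positions are therefore not integer pixel numbers).  By default the
    line is oversampled 4x relative to its pixel length.
    """
    h, w = image.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise InvalidParameterError(f"profile endpoint {p} outside image")
    length = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    if length == 0:
        raise InvalidParameterError("profile endpoints coincide")
    if n_samples is None:
        n_samples = max(8, int(np.ceil(4 * length)) + 1)
    if n_samples < 2:
        raise InvalidParameterError("need at least 2 samples")
    t = np.linspace(0.0, 1.0, n_samples)
    rows = p0[0] + t * (p1[0] - p0[0])
    cols = p0[1] + t * (p1[1] - p0[1])
    vals = ndimage.map_coordinates(
        image.pixels, np.vstack([rows, cols]), order=1, mode="nearest"
    )
    return t * length, vals


@dataclass(frozen=True)
class EdgeProfileFit:
    """Result of the Boltzmann (logistic) edge fit.

    ``width_10_90 == 2 * dx * ln 9`` holds by construction.
    """

    a_low: float
    a_high: float
    x0: float
    dx: float
    width_10_90: float
    rss: float

    def __post_init__(self) -> None:
        if not (self.a_high > self.a_low):
            raise FitFailureError("fit asymptotes inverted")
        if not (self.dx > 0):
            raise FitFailureError("fit slope parameter must be > 0")
        assert abs(self.width_10_90 - 2.0 * self.dx * LN9) <= 1e-9 * max(
            1.0, self.width_10_90
        )


def _logistic(x, a_low, a_high, x0, dx):
    return a_low + (a_high - a_low) * special.expit((x - x0) / dx)


def _smooth(y: np.ndarray) -> np.ndarray:
    k = max(3, len(y) // 20)
    k += 1 - k % 2
    return ndimage.uniform_filter1d(y, size=k, mode="nearest")


def fit_boltzmann(
    positions: np.ndarray, intensities: np.ndarray, max_restarts: int = 5
) -> EdgeProfileFit:
    """Least-squares logistic fit of an edge profile; width = 2*dx*ln 9.

    The profile must contain at least 8 samples and look like a single edge:
    its (smoothed) values must sit on opposite sides of the midrange at the
    two ends and cross it once.  Initialization follows the profile's 5th/95th
    percentiles, the midrange crossing, and a finite-difference slope; up to
    ``max_restarts`` jittered restarts are attempted on failure.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or len(x) < 8:
        raise InvalidParameterError("need >= 8 (position, intensity) samples")

    falling = y[: len(y) // 4].mean() > y[-len(y) // 4 :].mean()
    if falling:
        y = y[::-1].copy()

    ys = _smooth(y)
    lo, hi = np.percentile(y, [5, 95])
    if hi <= lo:
        raise NonEdgeProfileError("profile has no intensity range")
    mid = 0.5 * (lo + hi)
    q = len(y) // 4
    if not (ys[:q].mean() < mid < ys[-q:].mean()):
        raise NonEdgeProfileError("profile ends do not straddle the midrange")
    crossings = np.flatnonzero(np.diff(np.sign(ys - mid)) != 0)
    if len(crossings) == 0:
        raise NonEdgeProfileError("profile does not cross its midrange")
    if len(crossings) > 1 and (x[crossings[-1]] - x[crossings[0]]) > 0.25 * (
        x[-1] - x[0]
    ):
        raise NonEdgeProfileError("profile crosses its midrange in distant places")

    i0 = int(crossings[0])
    x0_init = float(x[i0])
    span = x[-1] - x[0]
    grad = np.gradient(ys, x)
    slope = max(float(grad[i0]), (hi - lo) / span)
    dx_init = float(np.clip((hi - lo) / (4.0 * slope), 1e-3 * span, span))

    rng = np.random.default_rng(0)
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        p0 = [lo, hi, x0_init, dx_init]
        if attempt > 0:
            p0 = [
                lo + rng.normal(0, 0.05 * (hi - lo)),
                hi + rng.normal(0, 0.05 * (hi - lo)),
                float(np.clip(x0_init + rng.normal(0, 0.05 * span), x[0], x[-1])),
                dx_init * float(np.exp(rng.normal(0, 0.7))),
            ]
        try:
            popt, _ = optimize.curve_fit(
                _logistic,
                x,
                y,
                p0=p0,
                bounds=([-np.inf, -np.inf, x[0] - span, 1e-9],
                        [np.inf, np.inf, x[-1] + span, 10 * span]),
                maxfev=20000,
            )
            a_low, a_high, x0, dx = map(float, popt)
            if a_high <= a_low:
                raise FitFailureError("inverted asymptotes")
            rss = float(np.sum((y - _logistic(x, *popt)) ** 2))
            if falling:
                x0 = float(x[-1] + x[0]) - x0
            return EdgeProfileFit(
                a_low=a_low, a_high=a_high, x0=x0, dx=dx,
                width_10_90=2.0 * dx * LN9, rss=rss,
            )
        except (RuntimeError, FitFailureError) as err:  # curve_fit non-convergence
            last_err = err
    raise FitFailureError(f"Boltzmann fit failed after restarts: {last_err}")


def blurriness_metric(
    image: GrayImage,
    p0: tuple[float, float],
    p1: tuple[float, float],
) -> float:
    """10-90% edge-spread width (profile units) along the given line."""
    pos, vals = extract_profile(image, p0, p1)
    return fit_boltzmann(pos, vals).width_10_90


@dataclass(frozen=True)
class QualityReport:
    """Raw and original-normalized metrics for one enhancement arm."""

    arm: str
    contrast: float
    snr: float
    blurriness: float
    contrast_norm: float | None = None
    snr_norm: float | None = None
    blurriness_norm: float | None = None


def normalize_reports(
    arm_reports: list[QualityReport], original_arm: str = "original"
) -> list[QualityReport]:
    """Divide every metric by the original arm's value (original row -> 1.0)."""
    ref = next((r for r in arm_reports if r.arm == original_arm), None)
    if ref is None:
        raise InvalidParameterError(f"arm {original_arm!r} missing")
    for name in ("contrast", "snr", "blurriness"):
        if getattr(ref, name) == 0:
            raise DegenerateRegionError(f"original arm has zero {name}")
    return [
        replace(
            r,
            contrast_norm=r.contrast / ref.contrast,
            snr_norm=r.snr / ref.snr,
            blurriness_norm=r.blurriness / ref.blurriness,
        )
        for r in arm_reports
    ]


def profile_minmax_match(profiles: list[np.ndarray]) -> list[np.ndarray]:
    """Affinely rescale every profile to share the first profile's min and max."""
    if not profiles:
        raise InvalidParameterError("no profiles given")
    ref = np.asarray(profiles[0], dtype=float)
    rmin, rmax = float(ref.min()), float(ref.max())
    if rmax <= rmin:
        raise DegenerateRegionError("reference profile is flat")
    out = []
    for p in profiles:
        p = np.asarray(p, dtype=float)
        pmin, pmax = float(p.min()), float(p.max())
        if pmax <= pmin:
            raise DegenerateRegionError("flat profile cannot be matched")
        out.append((p - pmin) / (pmax - pmin) * (rmax - rmin) + rmin)
    return out
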