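"""Mask-based MSSD tumor tracking and accuracy evaluation.

A binary mask drawn around the tumor on a reference frame defines a
template.  For every subsequent frame the mask is moved pixel-by-pixel over
a fixed search window and the mean of the sum of squared differences (MSSD)
between the reference intensities under the mask and the frame is evaluated
at each integer offset; the unique global minimum is the tracked position.
If the minimum is attained at more than one offset (within a tie tolerance)
the frame is declared undetected — weak contrast can leave several offsets
with indistinguishable scores.

Accuracy is referred to a manually-selected feature origin Tm(k) (here, the
mean of three feature points).  With Tt(k) the tracked position, the
relative distance vector is d(k) = Tm(k) - Tt(k) (in mm) and the tracking
error after removing the reference-frame offset is e(k) = d(k) - d(0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import measure

from .errors import InvalidParameterError, TrackingError
from .image import GrayImage

__all__ = [
    "TumorMask",
    "SearchWindow",
    "FrameTrackResult",
    "TrackingSummary",
    "manual_origin",
    "build_mask",
    "mssd_score",
    "locate_tumor",
    "evaluate_accuracy",
    "summarize_errors",
]


@dataclass(frozen=True)
class TumorMask:
    """Binary template tied to a reference frame.

    ``rows``/``cols`` are the masked pixel coordinates, ``reference_patch``
    the reference-frame intensities at those pixels, and ``center`` the mask
    centroid (the position reported for offset (0, 0)).
    """

    rows: np.ndarray
    cols: np.ndarray
    reference_patch: np.ndarray
    reference_frame_index: int
    roi_polygon: tuple[tuple[float, float], ...]
    frame_shape: tuple[int, int]

    @property
    def center(self) -> tuple[float, float]:
        return (float(self.rows.mean()), float(self.cols.mean()))

    @property
    def n_pixels(self) -> int:
        return int(len(self.rows))


@dataclass(frozen=True)
class SearchWindow:
    """Integer-offset search region.

    ``half_width_px`` h gives a (2h)x(2h) grid of offsets, h=5 being the
    10x10-pixel region (7.8 x 7.8 mm^2 at 0.784 mm pixels).  Offsets run
    from -h to h-1 inclusive in each axis, relative to the mask's reference
    position shifted by ``center_offset``.
    """

    half_width_px: int = 5
    center_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.half_width_px < 1:
            raise InvalidParameterError("half_width_px must be >= 1")

    def offsets(self) -> np.ndarray:
        h = self.half_width_px
        dr, dc = np.meshgrid(np.arange(-h, h), np.arange(-h, h), indexing="ij")
        off = np.stack([dr + self.center_offset[0], dc + self.center_offset[1]], -1)
        return off.reshape(-1, 2)


@dataclass(frozen=True)
class FrameTrackResult:
    """Per-frame tracking outcome.

    ``tracked_pos`` (Tt) and ``manual_origin`` (Tm) are (row, col); ``d_mm``
    is Tm - Tt scaled to mm, ``e_mm`` is d(k) - d(0).  ``mssd_surface`` holds
    the full score grid over the search window for inspection.
    """

    frame_index: int
    detected: bool
    offset: tuple[int, int] | None
    tracked_pos: tuple[float, float] | None
    manual_origin: tuple[float, float] | None
    mssd_surface: np.ndarray
    d_mm: tuple[float, float] | None = None
    e_mm: tuple[float, float] | None = None


@dataclass(frozen=True)
class TrackingSummary:
    """Per-axis error statistics over detected non-reference frames.

    Rows map to the superior-inferior axis, columns to left-right; values
    are the mean and sample SD of the absolute error components in mm.
    """

    arm: str
    mean_si_mm: float
    sd_si_mm: float
    mean_lr_mm: float
    sd_lr_mm: float
    n_frames: int
    n_detected: int
    n_undetected: int


def manual_origin(points) -> tuple[float, float]:
    """Mean of exactly three manually selected feature points."""
    pts = np.asarray(points, dtype=float)
    if pts.shape != (3, 2):
        raise InvalidParameterError("exactly three (row, col) points required")
    m = pts.mean(axis=0)
    return (float(m[0]), float(m[1]))


def build_mask(
    reference_frame: GrayImage,
    roi_polygon,
    frame_index: int = 0,
) -> TumorMask:
    """Rasterize an ROI polygon into a binary mask and extract the template.

    A pixel belongs to the mask when its center (integer coordinates) lies
    inside the polygon (even-odd rule).
    """
    poly = np.asarray(roi_polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise InvalidParameterError("ROI polygon needs >= 3 (row, col) vertices")
    # shoelace area; collinear/degenerate polygons rasterize to nothing useful
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if area < 1e-9:
        raise InvalidParameterError("degenerate (collinear) ROI polygon")
    h, w = reference_frame.shape
    if poly[:, 0].min() < -0.5 or poly[:, 1].min() < -0.5 or poly[:, 0].max() > h - 0.5 \
            or poly[:, 1].max() > w - 0.5:
        raise InvalidParameterError("ROI polygon outside the frame")

    r0 = max(0, int(np.floor(poly[:, 0].min())))
    r1 = min(h - 1, int(np.ceil(poly[:, 0].max())))
    c0 = max(0, int(np.floor(poly[:, 1].min())))
    c1 = min(w - 1, int(np.ceil(poly[:, 1].max())))
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    inside = measure.points_in_poly(pts, poly)
    if not inside.any():
        raise InvalidParameterError("ROI polygon rasterizes to an empty mask")
    rows = rr.ravel()[inside]
    cols = cc.ravel()[inside]
    return TumorMask(
        rows=rows,
        cols=cols,
        reference_patch=reference_frame.pixels[rows, cols].copy(),
        reference_frame_index=frame_index,
        roi_polygon=tuple((float(a), float(b)) for a, b in poly),
        frame_shape=(h, w),
    )


def mssd_score(mask: TumorMask, object_frame: GrayImage, offset) -> float:
    """Mean of squared differences between the template and the frame at an offset."""
    dr, dc = int(offset[0]), int(offset[1])
    h, w = object_frame.shape
    rows = mask.rows + dr
    cols = mask.cols + dc
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
        raise InvalidParameterError("shifted mask footprint outside the frame")
    diff = mask.reference_patch - object_frame.pixels[rows, cols]
    return float(np.mean(diff * diff))


def locate_tumor(
    mask: TumorMask,
    object_frame: GrayImage,
    window: SearchWindow | None = None,
    tie_tol: float = 1e-9,
    frame_index: int = 0,
    manual_origin_pos: tuple[float, float] | None = None,
) -> FrameTrackResult:
    """Exhaustive integer-pixel MSSD search over the window.

    Detected iff the global minimum is attained at exactly one offset within
    the relative tie tolerance; otherwise the frame is undetected and no
    position is reported.
    """
    if window is None:
        window = SearchWindow()
    offs = window.offsets()
    side = 2 * window.half_width_px
    scores = np.empty(len(offs))
    for i, (dr, dc) in enumerate(offs):
        scores[i] = mssd_score(mask, object_frame, (dr, dc))
    surface = scores.reshape(side, side)
    smin = scores.min()
    ties = scores <= smin + tie_tol * abs(smin)
    n_ties = int(ties.sum())
    if n_ties == 1:
        i = int(np.argmin(scores))
        dr, dc = int(offs[i, 0]), int(offs[i, 1])
        cr, ccol = mask.center
        return FrameTrackResult(
            frame_index=frame_index,
            detected=True,
            offset=(dr, dc),
            tracked_pos=(cr + dr, ccol + dc),
            manual_origin=manual_origin_pos,
            mssd_surface=surface,
        )
    return FrameTrackResult(
        frame_index=frame_index,
        detected=False,
        offset=None,
        tracked_pos=None,
        manual_origin=manual_origin_pos,
        mssd_surface=surface,
    )


def evaluate_accuracy(
    results: list[FrameTrackResult],
    pixel_spacing_mm: float,
    reference_index: int = 0,
) -> list[FrameTrackResult]:
    """Fill d(k) = Tm(k) - Tt(k) (mm) and e(k) = d(k) - d(0) for detected frames."""
    ref = next((r for r in results if r.frame_index == reference_index), None)
    if ref is None or not ref.detected:
        raise TrackingError("reference frame missing or undetected")
    if ref.manual_origin is None:
        raise TrackingError("reference frame lacks a manual origin")

    def d_of(r: FrameTrackResult) -> tuple[float, float]:
        return (
            (r.manual_origin[0] - r.tracked_pos[0]) * pixel_spacing_mm,
            (r.manual_origin[1] - r.tracked_pos[1]) * pixel_spacing_mm,
        )

    d0 = d_of(ref)
    out = []
    for r in results:
        if r.detected and r.manual_origin is not None:
            d = d_of(r)
            e = (d[0] - d0[0], d[1] - d0[1])
            out.append(replace(r, d_mm=d, e_mm=e))
        else:
            out.append(r)
    return out


def summarize_errors(
    results: list[FrameTrackResult],
    arm: str = "original",
    reference_index: int = 0,
) -> TrackingSummary:
    """Per-axis mean and sample SD of |e(k)| over detected non-reference frames."""
    non_ref = [r for r in results if r.frame_index != reference_index]
    detected = [r for r in non_ref if r.detected and r.e_mm is not None]
    if not detected:
        raise TrackingError("no detected non-reference frames to summarize")
    e = np.abs(np.array([r.e_mm for r in detected]))
    sd = e.std(axis=0, ddof=1) if len(detected) > 1 else np.array([0.0, 0.0])
    return TrackingSummary(
        arm=arm,
        mean_si_mm=float(e[:, 0].mean()),
        sd_si_mm=float(sd[0]),
        mean_lr_mm=float(e[:, 1].mean()),
        sd_lr_mm=float(sd[1]),
        n_frames=len(non_ref),
        n_detected=len(detected),
        n_undetected=len(non_ref) - len(detected),
    )
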