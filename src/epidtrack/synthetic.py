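"""Synthetic scenes with known ground truth.

Two scene families stand in for the undeposited raw data:

* a bar-pattern quality phantom in the spirit of the QC-3 plate: graded
  attenuation zones, low-contrast white/black reference patches, five bar
  groups at distinct spatial frequencies, a dark graticule, and a tilted
  plate/open-field edge for the edge-spread (blurriness) measurement;
* cine sequences of a low-contrast, smooth-edged elliptical "tumor" moving
  over a structured background (beam-profile gradient plus rib-like bands).

Both are degraded with the Lorentzian-PSF forward model so that every
downstream stage (enhancement, metrics, tracking) can be validated against
exact ground truth.

Intensity scale.  Scenes are laid out in arbitrary detector counts.  The
white/black reference patches differ by only ~2% — the defining feature of
megavoltage imaging, where Compton-dominated interactions leave almost no
differential attenuation — while the open beam around the plate and a dark
lead-like graticule give the image a wide overall dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError
from .image import GrayImage, degrade_image, lorentzian_psf

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "make_qc3_phantom",
    "make_cine_sequence",
    "default_phantom_scene",
    "default_cine_scene",
    "sinusoidal_trajectory",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic scene (phantom or cine).

    ``background_level`` is the open-beam intensity for the phantom and the
    mean anatomical background for cine scenes.  ``tumor_contrast`` is the
    fractional intensity decrement of the blob relative to its local
    background.  ``white_level``/``black_level`` are the phantom reference
    patch intensities.  ``noise_sd`` is the additive Gaussian noise standard
    deviation in counts; ``quantize`` rounds degraded frames to integer
    counts as a detector would.
    """

    image_shape: tuple[int, int] = (384, 512)
    pixel_spacing_mm: float = 0.784
    background_level: float = 1400.0
    white_level: float = 612.0
    black_level: float = 600.0
    tumor_contrast: float = 0.02
    tumor_radius_px: float = 7.0
    trajectory: tuple[tuple[int, int], ...] = ((0, 0),)
    noise_sd: float = 10.0
    psf_lambda: float = 0.5
    seed: int = 0
    search_half_width_px: int = 5
    quantize: bool = True

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h < 16 or w < 16:
            raise InvalidParameterError("image_shape must be at least 16x16")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if not (self.psf_lambda > 0):
            raise InvalidParameterError("psf_lambda must be > 0")
        if not (self.tumor_radius_px > 1):
            raise InvalidParameterError("tumor_radius_px must be > 1")
        if not (self.black_level > 0 and self.white_level > self.black_level):
            raise InvalidParameterError("need white_level > black_level > 0")
        if len(self.trajectory) == 0:
            raise InvalidParameterError("trajectory must be non-empty")
        hw = self.search_half_width_px
        for dr, dc in self.trajectory:
            if not (-hw <= dr < hw and -hw <= dc < hw):
                raise InvalidParameterError(
                    f"trajectory offset ({dr},{dc}) outside the tracker "
                    f"search window (half-width {hw})"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Exact annotations for a generated scene.

    Boxes are (row0, col0, row1, col1), half-open.  ``edge_p0``/``edge_p1``
    are the endpoints of the profile line crossing the tilted edge.  For cine
    scenes ``centers`` holds the true blob center per frame.
    """

    white_box: tuple[int, int, int, int] | None = None
    black_box: tuple[int, int, int, int] | None = None
    edge_p0: tuple[float, float] | None = None
    edge_p1: tuple[float, float] | None = None
    bar_groups: tuple[dict, ...] = ()
    centers: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.white_box is not None and self.black_box is not None:
            for box in (self.white_box, self.black_box):
                r0, c0, r1, c1 = box
                if r1 - r0 < 10 or c1 - c0 < 10:
                    raise InvalidParameterError("metric boxes must be >= 10x10")
            wr0, wc0, wr1, wc1 = self.white_box
            br0, bc0, br1, bc1 = self.black_box
            if not (wr1 <= br0 or br1 <= wr0 or wc1 <= bc0 or bc1 <= wc0):
                raise InvalidParameterError("metric boxes must not overlap")


def default_phantom_scene(seed: int = 0) -> SceneConfig:
    """The frozen phantom study conditions."""
    return SceneConfig(seed=seed)


def default_cine_scene(seed: int = 0, n_frames: int = 16) -> SceneConfig:
    """The frozen cine study conditions: weak-contrast moving blob.

    The blob decrement is only 2% of the local background — a few integer
    counts once quantized — which, like the patient data, puts the original
    arm at the edge of detectability (similar pixel values inside the mask
    search region can tie the match score).
    """
    return SceneConfig(
        image_shape=(128, 160),
        background_level=600.0,
        tumor_contrast=0.02,
        tumor_radius_px=7.0,
        trajectory=sinusoidal_trajectory(n_frames),
        noise_sd=3.0,
        seed=seed,
    )


def sinusoidal_trajectory(
    n_frames: int,
    amp_si: float = 4.0,
    amp_lr: float = 2.0,
    period: float = 10.0,
) -> tuple[tuple[int, int], ...]:
    """Breathing-like integer-pixel trajectory (rounded sinusoid).

    Superior–inferior motion maps to image rows, left–right to columns; the
    default 4-pixel SI amplitude is ~3 mm at 0.784 mm pixels.
    """
    k = np.arange(n_frames)
    rows = np.rint(amp_si * np.sin(2 * np.pi * k / period)).astype(int)
    cols = np.rint(amp_lr * np.sin(2 * np.pi * k / period + 0.8)).astype(int)
    return tuple((int(r), int(c)) for r, c in zip(rows, cols))


# ---------------------------------------------------------------------------
# phantom


def _phantom_layout(cfg: SceneConfig):
    """Compute the parametric geometry of the phantom for a given shape."""
    h, w = cfg.image_shape
    if h < 96 or w < 128:
        raise InvalidParameterError(
            "phantom needs at least 96x128 pixels for 5 bar groups, "
            "2 reference squares and a tilted edge"
        )
    th, tw = h // 8, w // 8  # CLAHE-tile-sized layout cells
    box = max(10, round(h / 32))
    inset = box + 4

    def tile_center(i, j):
        return (round((i + 0.5) * th), round((j + 0.5) * tw))

    white_c = tile_center(2, 1)
    black_c = tile_center(2, 5)
    layout = {
        "margin": (th, tw),
        "box": box,
        "inset": inset,
        "white_center": white_c,
        "black_center": black_c,
        "zone_rows": (2 * th, 3 * th),
        "bar_rows": (4 * th, 4 * th + max(12, round(0.16 * h))),
        "graticule": (
            round(6.05 * th), round(6.05 * th) + max(8, round(h / 12)),
            round(1.5 * tw), round(1.5 * tw) + max(8, round(h / 12)),
        ),
        "edge_slope": 0.08,
    }
    # bar groups: 5 widths, 3 bars each, gap between groups
    widths = (2, 3, 4, 6, 8)
    n_bars = 3
    gap = 4
    total = sum(2 * wd * n_bars for wd in widths) + gap * (len(widths) - 1)
    x0 = tw + max(4, tw // 8)
    edge_margin = round(layout["edge_slope"] * h / 2) + 6
    if x0 + total > w - tw - edge_margin:
        raise InvalidParameterError("image_shape too small for the bar groups")
    layout["bars"] = (x0, widths, n_bars, gap)
    return layout


def make_qc3_phantom(config: SceneConfig) -> tuple[GrayImage, GroundTruth]:
    """Generate the pristine (pre-degradation) quality phantom.

    Returns the ideal image and its annotations: the white and black metric
    boxes, the endpoints of the profile line crossing the tilted
    plate/open-field edge, and the bar-group geometry.
    """
    lay = _phantom_layout(config)
    h, w = config.image_shape
    th, tw = lay["margin"]
    plate = config.black_level
    white = config.white_level
    of = config.background_level

    img = np.full((h, w), plate)
    img[:th, :] = of
    img[-th:, :] = of
    img[:, :tw] = of
    img[:, -tw:] = of

    # tilted plate/open-field edge replacing the straight right margin
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    edge_col = (w - tw) - lay["edge_slope"] * (rr - h / 2)
    body = (rr >= th) & (rr < h - th)
    img[body & (cc > edge_col)] = of

    ins = lay["inset"]
    box = lay["box"]

    def rect(center, side):
        r, c = center
        return (r - side // 2, c - side // 2, r - side // 2 + side, c - side // 2 + side)

    # white patch in plate surround + dark graded zone strip in the same cell
    wr0, wc0, wr1, wc1 = rect(lay["white_center"], ins)
    img[wr0:wr1, wc0:wc1] = white
    zr0, zr1 = lay["zone_rows"]
    img[zr0:zr1, tw : tw + max(8, tw // 5)] = plate * 5 / 6

    # black patch in white surround + bright graded zone strip in the same cell
    br, bc = lay["black_center"]
    img[zr0:zr1, 5 * tw : 6 * tw] = white
    br0, bc0, br1, bc1 = rect((br, bc), ins)
    img[br0:br1, bc0:bc1] = plate
    img[zr0:zr1, 6 * tw - max(8, tw // 5) : 6 * tw] = plate * 1.25

    # two more graded attenuation zones
    img[zr0:zr1, round(2.5 * tw) : round(3.5 * tw)] = plate * 11 / 12
    img[zr0:zr1, round(3.75 * tw) : round(4.75 * tw)] = plate * 13 / 12

    # bar groups (alternating plate / bright)
    bar_r0, bar_r1 = lay["bar_rows"]
    x0, widths, n_bars, gap = lay["bars"]
    bar_level = plate * 13 / 12
    bar_groups = []
    x = x0
    for wd in widths:
        for i in range(n_bars):
            img[bar_r0:bar_r1, x + 2 * i * wd : x + 2 * i * wd + wd] = bar_level
        bar_groups.append(
            {"row": (bar_r0 + bar_r1) // 2, "col0": x, "col1": x + 2 * n_bars * wd,
             "bar_width": wd, "n_bars": n_bars}
        )
        x += 2 * n_bars * wd + gap

    # dark graticule square
    gr0, gr1, gc0, gc1 = lay["graticule"]
    img[gr0:gr1, gc0:gc1] = 0.1 * plate

    # blurriness profile line: horizontal, crossing the tilted edge at 3/4 height
    pr = 0.75 * h
    pc = (w - tw) - lay["edge_slope"] * (pr - h / 2)
    half_len = min(24, tw - 2, round(0.05 * w))
    p0 = (pr, pc - half_len)
    p1 = (pr, pc + half_len)

    gt = GroundTruth(
        white_box=rect(lay["white_center"], box),
        black_box=rect(lay["black_center"], box),
        edge_p0=p0,
        edge_p1=p1,
        bar_groups=tuple(bar_groups),
    )
    return GrayImage(img, config.pixel_spacing_mm), gt


# ---------------------------------------------------------------------------
# cine


def _cine_background(cfg: SceneConfig) -> np.ndarray:
    """Static structured background: beam-profile gradient + rib-like bands."""
    h, w = cfg.image_shape
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    base = cfg.background_level * (
        1.0
        + 0.08 * (cc - w / 2) / (w / 2)
        - 0.05 * ((rr - h / 2) / (h / 2)) ** 2
    )
    # rib-like horizontal bands, slightly tilted, smooth-edged
    phase = 2 * np.pi * (rr + 0.15 * cc) / 24.0
    bands = 1.0 - 0.05 * (0.5 + 0.5 * np.tanh(3.0 * np.sin(phase)))
    return base * bands


def _blob_factor(cfg: SceneConfig, center: tuple[float, float]) -> np.ndarray:
    """Multiplicative attenuation field of the smooth-edged elliptical blob."""
    h, w = cfg.image_shape
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    a = cfg.tumor_radius_px
    b = 0.8 * cfg.tumor_radius_px
    rho = np.sqrt(((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2)
    edge_w = 1.5 / a  # ~1.5 px wide sigmoid rim
    profile = 0.5 * (1.0 - np.tanh((rho - 1.0) / edge_w))
    return 1.0 - cfg.tumor_contrast * profile


def make_cine_sequence(config: SceneConfig) -> tuple[list[GrayImage], GroundTruth]:
    """Generate a degraded cine sequence with exact per-frame blob centers.

    Frame ``k`` places the blob at ``start + trajectory[k]`` over a fixed
    structured background; each frame is degraded independently (blur + noise
    + quantization), with per-frame noise streams derived from the scene seed.
    """
    h, w = config.image_shape
    start = (h // 2, w // 2)
    margin = config.tumor_radius_px + 4 + config.search_half_width_px
    for dr, dc in config.trajectory:
        r, c = start[0] + dr, start[1] + dc
        if not (margin <= r < h - margin and margin <= c < w - margin):
            raise InvalidParameterError("blob leaves the frame along the trajectory")

    bg = _cine_background(config)
    psf = lorentzian_psf(
        config.psf_lambda, pixel_spacing_mm=config.pixel_spacing_mm
    )
    seeds = np.random.SeedSequence(config.seed).generate_state(len(config.trajectory))
    frames: list[GrayImage] = []
    centers = []
    for k, (dr, dc) in enumerate(config.trajectory):
        center = (start[0] + dr, start[1] + dc)
        ideal = GrayImage(bg * _blob_factor(config, center), config.pixel_spacing_mm)
        frames.append(
            degrade_image(
                ideal, psf, config.noise_sd, int(seeds[k]), quantize=config.quantize
            )
        )
        centers.append(center)
    return frames, GroundTruth(centers=tuple(centers))
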