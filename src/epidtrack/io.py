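"""Reading and writing images and annotations.

Frames travel as TIFF/PNG (uint16 when intensities are integral and in
range, float32 TIFF otherwise); annotations (ground truth, boxes, ROI
polygons, feature points) as JSON.  Boxes are [row0, col0, row1, col1],
half-open; points are [row, col].
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as PILImage

from .errors import InvalidParameterError
from .image import GrayImage
from .synthetic import GroundTruth

__all__ = ["save_image", "load_image", "save_ground_truth", "load_ground_truth"]


def save_image(image: GrayImage, path) -> Path:
    path = Path(path)
    px = image.pixels
    integral = np.all(px == np.rint(px)) and px.max() < 2**16
    if path.suffix.lower() in (".tif", ".tiff"):
        data = px.astype(np.uint16) if integral else px.astype(np.float32)
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        if not integral:
            raise InvalidParameterError("PNG output requires integral intensities")
        PILImage.fromarray(px.astype(np.uint16)).save(path)
    else:
        raise InvalidParameterError(f"unsupported image format: {path.suffix}")
    return path


def load_image(path, pixel_spacing_mm: float) -> GrayImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        px = np.asarray(PILImage.open(path))
    else:
        raise InvalidParameterError(f"unsupported image format: {path.suffix}")
    return GrayImage(np.asarray(px, dtype=float), pixel_spacing_mm)


def save_ground_truth(gt: GroundTruth, path) -> Path:
    blob = {
        "white_box": list(gt.white_box) if gt.white_box else None,
        "black_box": list(gt.black_box) if gt.black_box else None,
        "edge_p0": list(gt.edge_p0) if gt.edge_p0 else None,
        "edge_p1": list(gt.edge_p1) if gt.edge_p1 else None,
        "bar_groups": [dict(b) for b in gt.bar_groups],
        "centers": {str(k): list(c) for k, c in enumerate(gt.centers)},
    }
    path = Path(path)
    path.write_text(json.dumps(blob, indent=2))
    return path


def load_ground_truth(path) -> GroundTruth:
    blob = json.loads(Path(path).read_text())
    centers = tuple(
        tuple(blob["centers"][str(k)]) for k in range(len(blob.get("centers", {})))
    )
    return GroundTruth(
        white_box=tuple(blob["white_box"]) if blob.get("white_box") else None,
        black_box=tuple(blob["black_box"]) if blob.get("black_box") else None,
        edge_p0=tuple(blob["edge_p0"]) if blob.get("edge_p0") else None,
        edge_p1=tuple(blob["edge_p1"]) if blob.get("edge_p1") else None,
        bar_groups=tuple(blob.get("bar_groups", [])),
        centers=centers,
    )
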