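#!/usr/bin/env python
"""Generate the two synthetic study scenes and write them with ground truth.

Produces, under results/scenes/:
  phantom/  - pristine and degraded quality phantom + annotations
  cine/     - the default weak-contrast cine sequence + per-frame truth

These are the inputs every later analysis step recomputes from (the scripts
regenerate in memory; the files are for inspection and external tools).
"""

import json
import warnings
from pathlib import Path

from epidtrack import (
    default_cine_scene,
    default_phantom_scene,
    lorentzian_psf,
    make_cine_sequence,
    make_qc3_phantom,
)
from epidtrack.image import degrade_image
from epidtrack.io import save_ground_truth, save_image

warnings.filterwarnings("ignore", message="PSF support half-width")

out = Path(__file__).resolve().parents[1] / "results" / "scenes"
(out / "phantom").mkdir(parents=True, exist_ok=True)
(out / "cine").mkdir(parents=True, exist_ok=True)

scene = default_phantom_scene(seed=0)
pristine, gt = make_qc3_phantom(scene)
psf = lorentzian_psf(scene.psf_lambda, pixel_spacing_mm=scene.pixel_spacing_mm)
degraded = degrade_image(pristine, psf, scene.noise_sd, scene.seed, quantize=True)
save_image(pristine, out / "phantom" / "pristine.tif")
save_image(degraded, out / "phantom" / "degraded.tif")
save_ground_truth(gt, out / "phantom" / "ground_truth.json")
print(f"phantom: {pristine.shape}, white box {gt.white_box}, black box {gt.black_box}")

cine = default_cine_scene(seed=0)
frames, cine_gt = make_cine_sequence(cine)
for k, fr in enumerate(frames):
    save_image(fr, out / "cine" / f"frame_{k:04d}.tif")
save_ground_truth(cine_gt, out / "cine" / "ground_truth.json")
print(f"cine: {len(frames)} frames of {frames[0].shape}, "
      f"blob contrast {cine.tumor_contrast:.3f}, noise sd {cine.noise_sd}")
print(f"wrote scenes to {out}")
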