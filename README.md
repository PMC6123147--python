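# epidtrack

Megavoltage (MV) portal images from an electronic portal imaging device
(EPID) are blurry, noisy and show very poor contrast — at 6 MV the
white/black reference patches of a QC-3 quality phantom differ by only a few
percent in intensity. This package implements and compares, end to end, the
three standard single-step enhancements of such images and measures what
each does to **markerless tumor tracking**:

* **deblurring** — total-variation (TV) regularized deconvolution,
* **contrast enhancement** — contrast-limited adaptive histogram
  equalization (CLAHE, 8×8 subsections),
* **denoising** — a 3×3 median filter.

Because raw EPID data of this kind is not publicly deposited, the package
ships a first-class synthetic-data module: a QC-3-like bar phantom and cine
sequences of a weak-contrast moving blob, both degraded by the detector's
Lorentzian point-spread function plus noise, with exact ground truth for
every annotation the analysis needs.

## The model and the measures

The observation is `g = H f + η`: ideal image `f`, blur `H` (a normalized
Lorentzian `(1 + r²/λ²)^(−3/2)` with λ = 0.5 mm at 6 MV), additive noise
`η`. Deblurring minimizes

```
μ ‖H f − g‖² + Σ √(βx² (Dx f)² + βy² (Dy f)²)
```

with gradient operators `Dx, Dy` (isotropic TV by default, βx = βy = 1).

Image quality is scored on the phantom by contrast `(Iw − Ib)/Iw`, SNR
`Iw/σb` (white/black reference boxes), and *blurriness* — the 10–90% width
`2·dx·ln 9` of a Boltzmann-sigmoid fit to a tilted-edge profile. All three
are reported normalized to the unenhanced image.

Tracking is mask-based template matching: a binary ROI mask on the
reference frame, moved pixel-by-pixel over a 10×10 search window; the
unique minimum of the mean sum of squared differences (MSSD) is the tracked
position `Tt(k)`. A non-unique minimum means the frame is *undetected*.
Accuracy per frame is `e(k) = d(k) − d(0)` with `d(k) = Tm(k) − Tt(k)` in
mm, where `Tm(k)` is a feature-based manual origin (mean of three points).

## Worked example

```python
from epidtrack import ExperimentConfig, run_phantom_experiment

report = run_phantom_experiment(ExperimentConfig(seed=0))
for arm, q in report.quality.items():
    print(f"{arm:10s} SNR={q.snr_norm:5.2f} "
          f"blurriness={q.blurriness_norm:5.2f} contrast={q.contrast_norm:6.2f}")
```

prints (seed 0):

```
original   SNR= 1.00 blurriness= 1.00 contrast=  1.00
deblurred  SNR=10.56 blurriness= 0.55 contrast=  0.83
clahe      SNR= 0.44 blurriness= 1.42 contrast= 11.08
denoised   SNR= 2.38 blurriness= 0.95 contrast=  1.00
```

Reading: deconvolution roughly halves the edge-spread width (sharper);
equalization multiplies the measured contrast by an order of magnitude at a
heavy SNR cost; the median filter buys SNR while leaving contrast and edge
width essentially unchanged. The numbered drivers under `analysis/` run the
same comparisons (`01` scene generation, `02` phantom quality, `03`
tracking accuracy, `04` detectability replicates, `05` min–max-matched
profiles) and write tables under `results/`.

A thin CLI wraps the same library calls:

```
epidtrack simulate cine --out scenes/cine --seed 1
epidtrack enhance in.tif out.tif --method tv
epidtrack metrics degraded.tif --boxes boxes.json --edge edge.json
epidtrack track --frames scenes/cine --roi roi.json --features feats.json
epidtrack compare --out results/
```

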