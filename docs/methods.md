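# Methods

## Forward model

An observed portal image is modeled as `g = H f + η`. `H` is convolution
with the detector point-spread function, sampled from the normalized
Lorentzian-to-the-3/2 profile `(1 + (x² + y²)/λ²)^(−3/2)` at pixel centers
(λ in mm; default 0.5 mm, the representative value for a 6 MV beam;
default pixel spacing 0.784 mm). The sampled kernel is renormalized to unit
sum and is exactly symmetric on the grid. `η` is zero-mean additive
Gaussian noise; degraded frames are optionally rounded to integer counts,
as a real detector reports them.

**PSF support.** The default kernel half-width is `ceil(6λ/spacing)`
pixels. The radial tail of this profile is heavy — the mass outside radius
R falls off like λ/R, so a 6λ support truncates roughly 14% of the
continuous mass. The constructor computes the truncation analytically and
warns when it exceeds 1% (the default therefore warns). The truncated
kernel is renormalized, and the *same* discrete kernel is used for forward
blurring and deconvolution, so the pipeline is self-consistent; users who
need the long tails can pass a larger support (about 100λ reaches the 1%
level). Convolution uses symmetric (mirror) boundary padding so flat
regions stay flat to the border and the metric boxes are never corrupted by
edge effects.

## TV deconvolution

The deblurred image minimizes
`μ‖Hf − g‖² + Σ √(βx²(Dxf)² + βy²(Dyf)² + ε)` with forward-difference
gradients, ε = 1e−12 smoothing the TV norm at zero gradient, and μ on the
data-fidelity term (the standard placement for this formulation). The
observed image is min–max normalized to [0, 1] before solving and restored
afterwards, which makes the default μ = 100 scale-free; μ was chosen by a
coarse grid on the synthetic phantom as the smallest order of magnitude
that clearly narrows the 10–90% edge width without ringing. βx = βy = 1
(isotropic). The solver is majorize–minimize (lagged diffusivity): at each
outer iteration the TV term is majorized by a weighted quadratic at the
current iterate and the resulting normal equations
`(2μHᵀH + DᵀWD) f = 2μHᵀg` are decreased by 8 conjugate-gradient steps
started from the current iterate. Because every inner step decreases the
quadratic majorizer, the recorded objective trace is monotonically
non-increasing — a property the tests assert. `H` is applied as a
frequency-domain product (periodic extension); the periodic/symmetric
boundary mismatch affects only a border of kernel width, far from any
measured region. Iterations stop after 200 outer steps or when the
relative objective change drops below 1e−5. The output is clipped to
non-negative intensities.

## CLAHE and median filter

Contrast enhancement uses contrast-limited adaptive histogram equalization
with the conventional defaults: an 8×8 subsection grid, clip limit 0.01
(fraction of the subsection pixel count per histogram bin), 256 bins,
bilinear blending between subsection mappings
(`skimage.exposure.equalize_adapthist`). Images are min–max scaled to
[0, 1] first and restored to the input range afterwards so all arms remain
on one intensity scale; a constant image passes through unchanged.
Denoising is a 3×3 median filter with mirror padding.

## Quality metrics

Contrast `(Iw − Ib)/Iw` and SNR `Iw/σb` use the mean intensities of a white
and a black reference box and the sample (n−1) standard deviation of the
black box. Blurriness is measured on a profile extracted by bilinear
interpolation along an annotated line crossing a tilted edge, oversampled
4× relative to its pixel length (positions are arc length in pixel units —
oblique lines do not sample at integer pixel numbers). A logistic
(Boltzmann) curve `a_low + (a_high − a_low)/(1 + exp(−(x − x0)/dx))` is fit
by nonlinear least squares; falling edges are reversed before fitting so
`a_high > a_low, dx > 0` always. Initialization: asymptotes from the
5th/95th percentiles, `x0` from the midrange crossing of a lightly smoothed
profile, `dx` from a finite-difference slope; up to five jittered restarts.
The 10–90% width is the closed form `2·dx·ln 9`, defined on the fitted
asymptotes rather than the sample extremes so single noise spikes cannot
masquerade as range. The edge-likeness precondition (ends straddle the
midrange; crossings confined to a quarter of the span) rejects bar-pattern
or flat profiles rather than returning a meaningless width.

At the default phantom noise level the fitted width has a replication
scatter of about ±3–4% between noise seeds. Comparisons smaller than that
band (the median-filter arm typically lands at 0.93–1.05 of the original
width) are read as "unchanged"; the deblurred arm lands near 0.55, far
outside it.

## Synthetic scenes

**Phantom.** The generated plate mimics the features a QC-3 portal image
offers the metrics, not its exact geometry: five bar groups at distinct
spatial frequencies, graded attenuation zones, a dark graticule, a bright
open-beam margin, a tilted plate/open-field edge for the width measurement,
and two small reference insets — a white patch in a plate-level surround
and a black patch in a white-level surround. Default intensities (counts):
open field 1400, plate 600, white 612, graticule 60, noise SD 10. The 2%
white/black separation is the defining MV condition: with Compton-dominated
interactions the raw patch contrast is tiny, which is precisely why
equalization changes the *measured* contrast by an order of magnitude
while a global affine map could not. The graded zones share the CLAHE
subsections with the reference insets so those subsections have broad
histograms; with narrow (spiky) histograms the clip limit redistributes
almost all mass and the per-subsection mapping collapses toward identity,
muting equalization — visible in any piecewise-constant synthetic scene,
and part of why real, textured portal images respond to CLAHE so strongly.
All metric regions are returned as annotations; no metric hard-codes
coordinates.

**Cine.** Frames hold a smooth-edged elliptical blob (radius 7 px, rim
~1.5 px, intensity decrement 2% of the local background) moving on a
breathing-like rounded sinusoid (±4 px superior–inferior ≈ 3 mm, ±2 px
left–right) over a *static* structured background: a beam-profile gradient
plus rib-like tilted bands. Each frame is degraded independently
(per-frame noise streams derived from the scene seed) and quantized to
integer counts. Defaults: 128×160 px, 16 frames, background 600 counts,
noise SD 3 — a desk-scale stand-in for 512×384 patient cine series; the
problem sizes keep the full test suite and the acceptance script within a
few minutes on one CPU.

What the generator does *not* emulate: anatomy that moves with the target
(the background is fixed, so at very low blob contrast the matcher is
pulled toward the background-aligned offset — the deterministic part of the
~1.5–2 mm tracking errors), deformation, out-of-plane rotation, scatter
glare, or detector lag. Passing tests therefore show the pipeline's
internal correctness and the direction of enhancement effects, not
clinical-grade accuracy numbers.

## Tracking

The ROI polygon (here a 16-gon circle at 1.4× the blob radius on frame 0)
is rasterized by the even-odd rule on pixel centers. The MSSD is the mean
over masked pixels of squared intensity differences; the search window is
the 10×10 integer-offset grid (offsets −5…4, i.e. 7.8×7.8 mm² at 0.784 mm
pixels) centered on the mask's reference position — no motion prediction,
trajectories are validated to stay inside the window. A frame is detected
only if the global minimum is unique within a relative tie tolerance of
1e−9; equal integer-count scores therefore tie exactly and mark the frame
undetected. Applying one strictly increasing affine map to reference and
object frames scales every score by the gain squared and cannot change the
argmin — the mechanism by which equalized frames track exactly like the
originals. Equalized intensities are continuous, so exact ties essentially
cannot occur there, while quantized original frames can tie when the blob
contrast is within a few counts; at the default cine conditions such ties
are rare (a few per thousand frames), so the detectability comparison is
reported as a fraction of replicates rather than a count.

Feature origins stand in for manual selection: three fixed offsets from the
true blob center plus Gaussian jitter (SD 0.5 px). Error summaries use the
absolute per-axis components of `e(k)` (mean and sample SD, mm) over
detected non-reference frames; undetected frames are excluded. Rows map to
superior–inferior, columns to left–right.

## Numerical and design choices

* Tie tolerance 1e−9 (relative) on MSSD scores; configurable.
* σb uses ddof = 1; boxes must be ≥10×10 px, disjoint, in bounds.
* The reference frame is enhanced with the same operator as the object
  frames in each arm; matching is relative, so arms stay comparable.
* Quality metrics are computed only in the phantom experiment; the cine
  experiment reports tracking quantities.
* Degenerate inputs raise typed errors (`InvalidParameterError`,
  `DegenerateRegionError`, `NonEdgeProfileError`, `TrackingError`,
  `SolverFailureError`) rather than returning sentinel values.

## Known limitations

* The TV solver is a general-purpose monotone scheme, not tuned for speed;
  deblurring a 384×512 image takes ~20 s at default settings.
* The blurriness metric summarizes one edge; it does not see fogged fine
  bars elsewhere in the image (a denoised image can lose bar detail while
  its edge-width ratio stays ≈1 — the metric reproduces that blind spot).
* λ and pixel spacing are independent inputs; no rescaling of λ across
  detectors with different resolution is attempted.
* Detection ties depend on integer quantization; unquantized synthetic
  frames essentially never tie.
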