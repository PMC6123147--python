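#!/usr/bin/env python
"""Four-arm quality comparison on the degraded phantom.

Degrades the phantom once, applies TV deconvolution, CLAHE and the median
filter to the same image, measures contrast, SNR and 10-90% edge width per
arm and normalizes to the original.  Writes results/table1.csv and prints
the normalized table (original row = 1.00 by construction).
"""

import warnings
from pathlib import Path

from epidtrack import ExperimentConfig, run_phantom_experiment, write_report

warnings.filterwarnings("ignore", message="PSF support half-width")

out = Path(__file__).resolve().parents[1] / "results"
rep = run_phantom_experiment(ExperimentConfig(seed=0))
paths = write_report(rep, out)

print(f"{'arm':10s} {'SNR':>7s} {'Blurriness':>11s} {'Contrast':>9s}")
for arm, q in rep.quality.items():
    print(f"{arm:10s} {q.snr_norm:7.2f} {q.blurriness_norm:11.2f} "
          f"{q.contrast_norm:9.2f}")
print(f"\nwrote {paths['table1']}")
print("reading: equalization multiplies the measured contrast roughly an "
      "order of magnitude\nat the cost of SNR; deconvolution narrows the edge "
      "spread; the median filter buys\nSNR and leaves contrast and width "
      "essentially unchanged.")
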