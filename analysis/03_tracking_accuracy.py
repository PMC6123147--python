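#!/usr/bin/env python
"""Four-arm tracking accuracy on the default cine sequence.

Enhances every frame per arm (reference included), tracks with the MSSD
mask matcher, and summarizes per-axis errors e(k) = d(k) - d(0) against
feature-based origins.  Writes results/table2.csv.
"""

import warnings
from pathlib import Path

from epidtrack import ExperimentConfig, run_tracking_experiment, write_report

warnings.filterwarnings("ignore", message="PSF support half-width")

out = Path(__file__).resolve().parents[1] / "results"
rep = run_tracking_experiment(ExperimentConfig(seed=0))
paths = write_report(rep, out)

print(f"{'arm':10s} {'SI mm':>12s} {'LR mm':>12s} {'detected':>9s}")
for arm, s in rep.tracking.items():
    print(f"{arm:10s} {s.mean_si_mm:5.2f} ({s.sd_si_mm:4.2f}) "
          f"{s.mean_lr_mm:5.2f} ({s.sd_lr_mm:4.2f}) "
          f"{s.n_detected:4d}/{s.n_frames}")
print(f"\nwrote {paths['table2']}")
print("reading: all arms localize the weak-contrast blob to within ~2 mm of "
      "the feature\norigin; enhancement changes the errors only marginally "
      "because matching is a\nrelative operation between identically "
      "processed frames.")
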