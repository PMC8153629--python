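#!/usr/bin/env python
"""T2* mapping accuracy on aorta-plaque phantoms.

Measures (a) voxelwise accuracy of the SNR-gated, outlier-filtered map at
first-echo SNR 50, (b) the benefit of the through-slice field-gradient
(sinc) correction under gradients up to 2 uT/mm, and (c) the slice-mean
ordering across injection time points (heavier iron load -> shorter T2*).
"""

import argparse
import json
from pathlib import Path

import numpy as np

from nemri.experiments import (
    sinc_correction_study,
    t2star_accuracy,
    t2star_timepoint_ordering,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=2)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

acc = t2star_accuracy(seed=args.seed, snr=50.0)
print(f"map accuracy at SNR 50: RMSE {acc.rmse_pct_of_truth:.2f}% of truth "
      f"({acc.n_valid} valid voxels; accounting {acc.counts})")

sinc = {}
for snr in (20.0, 50.0, float("inf")):
    s = sinc_correction_study(seed=args.seed + 1, snr=snr)
    sinc[str(snr)] = s
    print(f"sinc correction, SNR {snr}: RMSE {s['rmse_uncorrected_ms']:.2f} -> "
          f"{s['rmse_corrected_ms']:.2f} ms ({s['rmse_reduction_pct']:.0f}% reduction)")

ordering = t2star_timepoint_ordering(seed=args.seed)
print("slice-mean T2* by time point:",
      {k: round(v, 2) for k, v in ordering.items()},
      "(baseline > 24 h > 7 h)" if ordering["baseline"] > ordering["24h"] > ordering["7h"]
      else "(unexpected ordering!)")

summary = {
    "seed": args.seed,
    "rmse_pct_snr50": acc.rmse_pct_of_truth,
    "filter_counts": acc.counts,
    "sinc_correction": sinc,
    "timepoint_slice_means_ms": ordering,
}
(args.out / "t2star_summary.json").write_text(json.dumps(summary, indent=2, default=float))
print(f"-> {args.out/'t2star_summary.json'}")
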