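#!/usr/bin/env python
"""ESR spin quantification against a synthetic calibration series.

Builds the through-origin calibration line over 5e-10 to 1e-7 mol/g,
quantifies a sample at the tissue-level 1.7e-8 mol/g, and repeats with 5%
spectral noise to exercise the uncertainty propagation.
"""

import argparse
import json
from pathlib import Path

from nemri.experiments import esr_quant_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=3)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

summary = {"seed": args.seed}
for label, noise in [("noiseless", 0.0), ("noisy_5pct", 0.05)]:
    out = esr_quant_study(seed=args.seed, noise_frac=noise)
    summary[label] = out
    print(f"{label}: calibration R^2 = {out['calibration_r2']:.6f}; "
          f"recovered {out['recovered_concentration_mol_per_g']:.3g} "
          f"+/- {out['uncertainty_mol_per_g']:.2g} mol/g "
          f"(truth 1.7e-08, error {100*out['rel_error']:.2f}%); "
          f"p-p width {out['pp_width_mT']:.1f} mT")

(args.out / "esr_summary.json").write_text(json.dumps(summary, indent=2, default=float))
print(f"-> {args.out/'esr_summary.json'}")
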