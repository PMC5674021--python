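"""Simulate the study inputs: a fragmentation gradient and field data.

Writes, under results/inputs/:
  patch_table.csv   - county-style forest + core patch-class table for the
                      11-landscape synthetic gradient
  observations.csv  - noisy nest-survival and saturation-density field
                      observations around the default vital-rate curves

Run:  python analysis/01_simulate_inputs.py [--seed N]
"""

import argparse
from pathlib import Path

import numpy as np

from fragdd import synthetic_data, vital_rates

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", default="results/inputs")
args = parser.parse_args()

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)

cfg = synthetic_data.LandscapeGeneratorConfig(seed=args.seed)
landscapes = synthetic_data.generate_fragmentation_gradient(cfg)
synthetic_data.write_patch_table(landscapes, out / "patch_table.csv")

obs = synthetic_data.generate_vital_observations(
    vital_rates.SaturatingSurvivalCurve(),
    vital_rates.SigmoidDensityCurve(),
    sizes=np.geomspace(1.0, 500.0, 40),
    seed=args.seed,
)
synthetic_data.write_observations(obs, out / "observations.csv")

qs = [ls.quality for ls in landscapes]
print(f"wrote {len(landscapes)} landscapes to {out / 'patch_table.csv'}")
print(f"  quality Q spans {min(qs):.3f} .. {max(qs):.3f} "
      f"(fragmented -> contiguous)")
print(f"wrote {len(obs)} vital-rate observations to {out / 'observations.csv'}")
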