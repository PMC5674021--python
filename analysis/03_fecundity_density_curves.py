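"""Site-dependence occupancy curves and generalized Beverton-Holt fits.

For each landscape: fill patches largest-first to saturation density,
record (D(a), F(a)) per size-class threshold, fit F = F_max/(1+(D/K)^gamma),
and report how abruptness gamma varies with landscape quality Q.

Writes results/fecundity_density_points.csv and results/bh_fits.csv.

Run:  python analysis/03_fecundity_density_curves.py [--seed N]
"""

import argparse
from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

from fragdd import density_dependence, landscape, site_dependence, vital_rates

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--inputs", default="results/inputs")
parser.add_argument("--out", default="results")
args = parser.parse_args()

records = landscape.load_patch_table(Path(args.inputs) / "patch_table.csv")
landscapes = landscape.build_landscapes(records)
survival = vital_rates.SaturatingSurvivalCurve()
density_curve = vital_rates.SigmoidDensityCurve()

frames, rows = [], []
for ls in landscapes:
    series = site_dependence.occupancy_curve(
        ls.forest, survival, density_curve, landscape_id=ls.id
    )
    fit = density_dependence.fit_bh(series, seed=args.seed)
    frames.append(series.to_frame())
    rows.append(
        {"landscape_id": ls.id, "Q": ls.quality, "F_max": fit.F_max,
         "K": fit.K, "gamma": fit.gamma, "residual_ss": fit.residual_ss}
    )

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)
pd.concat(frames, ignore_index=True).to_csv(
    out / "fecundity_density_points.csv", index=False, float_format="%.10g"
)
fits = pd.DataFrame(rows)
fits.to_csv(out / "bh_fits.csv", index=False, float_format="%.10g")

rho = spearmanr(fits["gamma"], fits["Q"]).statistic
print(fits.to_string(index=False))
print(f"\nabruptness gamma rank-correlates with quality Q: "
      f"Spearman rho = {rho:+.3f}")
print("higher-quality (less fragmented) landscapes have more abruptly "
      "convex fecundity-density curves" if rho > 0 else
      "no positive abruptness-quality relation found")
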