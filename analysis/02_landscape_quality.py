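"""Aggregate county patch tables into landscapes and classify quality.

Reads results/inputs/patch_table.csv, writes results/landscapes.csv with
forest/core areas, Q = core/total, and the good/moderate/poor class.

Run:  python analysis/02_landscape_quality.py
"""

import argparse
from pathlib import Path

from fragdd import landscape

parser = argparse.ArgumentParser()
parser.add_argument("--inputs", default="results/inputs")
parser.add_argument("--out", default="results")
args = parser.parse_args()

records = landscape.load_patch_table(Path(args.inputs) / "patch_table.csv")
landscapes = landscape.build_landscapes(records)
table = landscape.summarize_landscapes(landscapes)
Path(args.out).mkdir(parents=True, exist_ok=True)
table.to_csv(Path(args.out) / "landscapes.csv", index=False, float_format="%.10g")

print(table.to_string(index=False))
counts = table["quality_class"].value_counts().to_dict()
print(f"\nquality classes: {counts}")
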