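"""Cluster reallocation: dilate each arm 0-1000 m and refit the trial model.

Under no spillover the estimate should drift toward SMR 1 as reassignment
dilutes the arms; a strong near-field spillover from the intervention would
instead strengthen the estimate while the buffer stays within the
spillover's functional range.  Writes results/reallocation_curve.csv and a
per-arm summary.
"""

import argparse
import json
from pathlib import Path

from crtspill import ModelSpec, curve_summary, read_trial, reallocation_sweep
from crtspill.data import distance_to_discordant

parser = argparse.ArgumentParser()
parser.add_argument("--trial", type=Path, default=Path("results/trial"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--seed", type=int, default=5)
args = parser.parse_args()

trial = distance_to_discordant(
    read_trial(args.trial / "households.csv", args.trial / "clusters.geojson")
)
curve = reallocation_sweep(trial, ModelSpec(random_structure="iid", seed=args.seed))
curve.table.to_csv(args.out / "reallocation_curve.csv", index=False, float_format="%.6f")

summary = curve_summary(curve)
with open(args.out / "reallocation_summary.json", "w") as f:
    json.dump(summary, f, indent=2)

print(curve.table.round(3).to_string(index=False))
print(f"original SMR {summary['original_smr']:.3f}")
for key in ("control_larger", "intervention_larger"):
    s = summary[key]
    print(f"{key:<20} mean {s['mean']:.3f} (min {s['min']:.3f}, max {s['max']:.3f})")
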