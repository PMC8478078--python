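"""Standardized growth index on a hand-built mini round.

Builds one experimental round (controls plus one inoculated treatment),
computes the round's control baseline, and expresses each treated plant
as control-SD units above the control mean.
"""

import pandas as pd

from synergy_screen import Trait, control_stats, standardize_dataset
from synergy_screen.standardization import SG_THRESHOLD_95

rows = [
    # plant_id, kind, isolate_a, isolate_b, round, shoot dry weight (mg), leaves, spad
    ("c1", "control", "", "", "R1", 90.0, 5, None),
    ("c2", "control", "", "", "R1", 100.0, 6, None),
    ("c3", "control", "", "", "R1", 110.0, 5, None),
    ("c4", "control", "", "", "R1", 100.0, 6, None),
    ("t1", "single", "ver_0232", "", "R1", 135.0, 7, None),
    ("t2", "single", "ver_0232", "", "R1", 150.0, 8, None),
    ("t3", "single", "ver_0232", "", "R1", 128.0, 7, None),
]
plants = pd.DataFrame(
    rows,
    columns=["plant_id", "treatment_kind", "isolate_a", "isolate_b", "round_id",
             "shoot_dry_weight", "n_mature_leaves", "spad"],
)

stats = control_stats(plants, "R1", Trait.SHOOT_DRY_WEIGHT)
print(f"control baseline: mean = {stats.mean:.1f} mg, SD = {stats.sd:.2f} mg "
      f"({stats.n_controls} control plants)")

sg = standardize_dataset(plants, traits=(Trait.SHOOT_DRY_WEIGHT,))
treated = sg[sg["treatment_kind"] == "single"]
print(treated[["plant_id", "treatment", "sg"]].to_string(index=False))
print(f"mean SG = {treated['sg'].mean():.2f}")

# SG is dimensionless: each value counts control standard deviations above
# the round's control mean, so |SG| > 1.96 marks a plant outside the
# controls' two-sided 95% range.
outside = (treated["sg"].abs() > SG_THRESHOLD_95).sum()
print(f"{outside}/{len(treated)} treated plants fall outside +/-{SG_THRESHOLD_95}")
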