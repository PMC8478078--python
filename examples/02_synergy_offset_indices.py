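"""Synergy (DMX), offset (DMN), and intermediate-deviation (DI) indices.

Scores a dual inoculation against its two single inoculations on the
standardized-growth scale: does the pair beat the better partner
(synergy), fall below the worse one (offset), or sit near their midpoint?
"""

import numpy as np
import pandas as pd

from synergy_screen import Trait, summarize_pair

rng = np.random.default_rng(0)

# standardized records: fus_0983 averages +2 SG alone, cur_0077 +3 SG
# alone, and the pair is generated 1.5 SG units above the two singles'
# midpoint (2.5), i.e. above even the better partner
rows = []
for v in rng.normal(2.0, 1.0, 25):
    rows.append(("single", "fus_0983", "", Trait.SHOOT_DRY_WEIGHT.value, v))
for v in rng.normal(3.0, 1.0, 25):
    rows.append(("single", "cur_0077", "", Trait.SHOOT_DRY_WEIGHT.value, v))
for v in rng.normal(2.5 + 1.5, 1.0, 25):
    rows.append(("dual", "cur_0077", "fus_0983", Trait.SHOOT_DRY_WEIGHT.value, v))

sg = pd.DataFrame(rows, columns=["treatment_kind", "isolate_a", "isolate_b", "trait", "sg"])
sg["round_id"] = "R1"
sg["plant_id"] = [f"p{i}" for i in range(len(sg))]

res = summarize_pair(sg, ("cur_0077", "fus_0983"), Trait.SHOOT_DRY_WEIGHT)
print(f"single means: m_A = {res.sg_a_mean:.2f}, m_B = {res.sg_b_mean:.2f}")
print(f"dual mean SG = {res.sg_ab_mean:.2f} over {res.n_dual} replicates")
print(f"DMX (above the better single) = {res.dmx_mean:+.2f}  -> synergistic: {res.synergistic}")
print(f"DMN (below the worse single)  = {res.dmn_mean:+.2f}  -> offset: {res.offset}")
print(f"DI  (above the midpoint)      = {res.di_mean:+.2f}")

# The identities DMX + DMN = -|m_A - m_B| and DI - DMX = |m_A - m_B|/2
# tie the three indices together for every replicate:
gap = abs(res.sg_a_mean - res.sg_b_mean)
print(f"identity check: DMX + DMN = {res.dmx_mean + res.dmn_mean:+.4f} "
      f"(expected {-gap:+.4f})")
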