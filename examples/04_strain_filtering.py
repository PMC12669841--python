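"""Ligament strain arithmetic and strain-threshold filtering.

Engineering strain is 100 * (length / rest - 1).  Poses whose ligament
lengths exceed a per-ligament maximum are removed from the viable set;
the filter is monotone in the thresholds.
"""

import numpy as np
import pandas as pd

from romkit import StrainThresholds, apply_strain_filter, compute_strain
from romkit.ligaments import Ligament
from romkit.mobility import derive_thresholds

print("worked strain examples:")
for frac in (1.395, 1.0, 0.054):
    print(f"  length = {100 * frac:5.1f}% of rest -> "
          f"{compute_strain(frac * 10.0, 10.0):+6.1f}% strain")

# Thresholds from scaled rest lengths plus a mean failure-strain factor.
ligs = [Ligament(name="LAcH", origin=[0, 0, 0], insertion=[1, 0, 0],
                 rest_length=12.0),
        Ligament(name="LCrCH", origin=[0, 0, 0], insertion=[0, 1, 0],
                 rest_length=9.0)]
thr = derive_thresholds("scaled_rest_plus_strain", ligaments=ligs,
                        strain_factor=0.26)
print(f"thresholds (rest * 1.26): {thr.max_length}")

# Filter a small synthetic pose table.
rng = np.random.default_rng(0)
table = pd.DataFrame({
    "len_LAcH": rng.uniform(10, 18, 200),
    "len_LCrCH": rng.uniform(8, 13, 200)})
viable = np.ones(200, dtype=bool)
kept = apply_strain_filter(viable, table, thr)
print(f"poses surviving the strain filter: {int(kept.sum())} / 200")

loose = StrainThresholds({k: v + 2.0 for k, v in thr.max_length.items()})
print(f"with +2 mm looser thresholds:     "
      f"{int(apply_strain_filter(viable, table, loose).sum())} / 200")
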