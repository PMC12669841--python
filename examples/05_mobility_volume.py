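"""Alpha-shape mobility volumes in sine-corrected pose space.

A 10x10x10-degree lattice cube should measure almost exactly 1000 deg^3,
and the missed-volume Monte-Carlo estimate of a set against itself is
zero.
"""

import numpy as np

from romkit import alpha_volume, missed_volume, sine_correct
from romkit.mobility import alpha_sensitivity

ax = np.arange(11, dtype=float)
cube = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"),
                axis=-1).reshape(-1, 3)
mv = alpha_volume(cube, alpha=2.0)
print(f"cube lattice: volume {mv.volume:.2f} deg^3 "
      f"({mv.n_components} component)")

print("alpha sensitivity:")
curve = alpha_sensitivity(cube, [1.0, 1.5, 2.0, 4.0, 8.0])
print(curve.to_string(index=False))

deg3, pct, se = missed_volume(cube, cube, alpha=2.0, n_samples=20_000)
print(f"missed volume of the cube vs itself: {deg3:.2f} deg^3 ({pct:.2f}%)")

# Volumes are compared in sine-corrected coordinates to avoid the
# area distortion of raw Euler angles away from zero abduction.
poses = np.array([[120.0, 60.0, -30.0], [120.0, 0.0, -30.0]])
print("sine-corrected coordinates of two poses:")
print(sine_correct(poses))
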