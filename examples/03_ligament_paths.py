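"""Shortest ligament path around an obstacle vs the taut-string oracle.

A ligament spanning a cylinder of radius r with endpoints at distance d
from the axis has the closed-form geodesic length
2*sqrt(d^2 - r^2) + r*(pi - 2*arccos(r/d)).  The discrete polyline
solver should approach it as the segment count grows.
"""

import numpy as np

from romkit import Obstacle, ligament_frame, solve_ligament_path
from romkit.fixtures import make_cylinder_obstacle

grid, _, _ = make_cylinder_obstacle(radius=0.5, half_extent=3.0,
                                    resolution=61)
frame = ligament_frame([-2, 0, 0], [2, 0, 0], [0, 5, 0])

d, r = 2.0, 0.5
exact = 2 * np.sqrt(d**2 - r**2) + r * (np.pi - 2 * np.arccos(r / d))
print(f"closed-form taut-string length: {exact:.6f} mm")
for n in (10, 20, 40):
    path = solve_ligament_path(frame, [Obstacle(grid)], n_segments=n)
    err = 100 * abs(path.length - exact) / exact
    print(f"  n={n:3d}: length {path.length:.6f} mm  ({err:.3f}% error, "
          f"converged={path.converged})")

free = solve_ligament_path(frame, [], n_segments=20)
print(f"no obstacle -> straight chord: {free.length:.6f} mm (exact 4.0)")
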