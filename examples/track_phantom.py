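"""Deterministic FACT tracking through a curved direction field.

Builds a rotational (circular) principal-direction phantom and checks that
the tracked streamline stays on the analytic circle.
"""

import numpy as np

from alongtract import TrackingConfig, fact_track

shape = (40, 40, 3)
center = np.array([5.0, 5.0])
peaks = np.zeros(shape + (3,))
fa = np.zeros(shape)
for i in range(shape[0]):
    for j in range(shape[1]):
        rel = np.array([i, j], float) - center
        r = np.linalg.norm(rel)
        if 8.0 <= r <= 16.0:
            peaks[i, j, :, :2] = np.array([-rel[1], rel[0]]) / r
            fa[i, j, :] = 0.8

mask = np.zeros(shape, dtype=bool)
mask[17, 5, 1] = True  # one seed at radius 12

config = TrackingConfig(step_size=0.5, max_turn_angle=30.0, min_length=5.0)
lines = fact_track(peaks, fa, config, mask)
radii = np.linalg.norm(lines[0][:, :2] - center, axis=1)
print(f"streamlines: {len(lines)}, points: {len(lines[0])}")
print(f"radius along the streamline: mean {radii.mean():.2f} mm "
      f"(target 12), RMS deviation {np.sqrt(np.mean((radii - 12) ** 2)):.2f} mm")
print("FACT follows the per-voxel principal direction, so the path hugs the "
      "analytic circle to within a voxel until it leaves the FA>0.2 band.")
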