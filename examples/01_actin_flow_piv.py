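"""Measure cortical actin flow by PIV on a synthetic time-lapse movie.

Generates a punctate actin texture drifting upward (toward the EVL-YSL
margin) at 0.5 µm/min, runs windowed cross-correlation PIV, filters
spurious vectors and summarizes direction and speed.
"""

import numpy as np

from yolkflow.piv import PivParams, compute_piv, directional_summary, filter_vectors
from yolkflow.synth import FlowScenario, NoiseModel, make_flow_stack

# Margin-directed flow, 0.5 s/frame acquisition, shot noise at 200
# photons per unit peak intensity.
scenario = FlowScenario(kind="uniform", vx=0.0, vy=-0.5, n_frames=12, seed=42,
                        noise=NoiseModel(photon_budget=200))
stack, truth = make_flow_stack(scenario, pixel_size=0.25, frame_interval=0.5,
                               shape=(300, 300))

params = PivParams(window_um=14.8, s2n_threshold=1.0, speed_cap=1.0)
fields = [filter_vectors(f, params) for f in compute_piv(stack, params)]
summary = directional_summary(fields, rose_bins=36)

print(f"valid vectors: {summary.n_valid}")
print(f"mean speed:    {summary.mean_speed_um_min:.3f} µm/min (true 0.500)")
print("quadrant fractions:",
      {k: round(v, 3) for k, v in summary.quadrant_fractions.items()})
# The up fraction near 1.0 confirms margin-directed flow; the mean speed
# reports its magnitude in physical units.
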