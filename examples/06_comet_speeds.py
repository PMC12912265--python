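"""Track EB3 comets and measure microtubule polymerization speed.

Two comets translate at 0.3 and 0.5 µm/s; detection, greedy linking and
path-length/duration speed measurement recover both.
"""

from yolkflow.puncta import comet_speeds, detect_comets, link_tracks
from yolkflow.synth import make_comet_stack

stack, truth = make_comet_stack(speeds=[0.3, 0.5], directions_deg=[0.0, 90.0],
                                n_frames=15, dt=0.5, pixel_size=0.1,
                                shape=(256, 256), seed=2)

detections = [detect_comets(frame, min_intensity=0.2) for frame in stack.frames]
tracks = link_tracks(detections, max_displacement_px=6.0, min_track_length=5)
tracks, mean_speed = comet_speeds(tracks, stack)

for i, tr in enumerate(tracks):
    print(f"track {i}: {tr.n_points} points, {tr.mean_speed_um_s:.3f} µm/s")
print(f"movie mean speed: {mean_speed:.3f} µm/s (true mean 0.400)")
# Comet speed approximates the microtubule plus-end polymerization rate.
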