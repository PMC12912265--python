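import numpy as np
import pytest

from yolkflow.io import CalibratedStack
from yolkflow.synth import render_spots


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_stack(rng):
    """10-frame 64x64 uint16 stack, 0.25 µm/px, 0.5 s/frame."""
    frames = rng.integers(0, 4096, size=(10, 64, 64), dtype=np.uint16)
    return CalibratedStack(frames=frames, pixel_size=0.25, frame_interval=0.5)


@pytest.fixture
def puncta_texture(rng):
    """Smooth punctate texture resembling labelled cortical actin."""
    h = w = 200
    n = int(0.5 * (h * 0.25) * (w * 0.25))
    pos = np.column_stack([rng.uniform(0, h, n), rng.uniform(0, w, n)])
    return render_spots((h, w), pos, sigma_px=1.4, periodic=True)


def shifted_pair_stack(base: np.ndarray, shift: tuple[int, int],
                       pixel_size: float = 0.25, frame_interval: float = 0.5) -> CalibratedStack:
    """Two-frame stack whose second frame is the first circularly shifted."""
    frames = np.stack([base, np.roll(base, shift, axis=(0, 1))])
    return CalibratedStack(frames=frames, pixel_size=pixel_size, frame_interval=frame_interval)
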