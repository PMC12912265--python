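"""Physical-unit conversions.

Every conversion between pixel/frame units and physical units (µm, s, min)
lives here and is reached through :class:`~yolkflow.io.CalibratedStack`
accessors. No other module multiplies by ``pixel_size`` or
``frame_interval`` directly; this keeps calibration handling auditable.

Image convention: row-major arrays, origin top-left, row index increases
downward. Oriented movies place the EVL–YSL margin at the top, so the
animal ("up") direction is decreasing row index.
"""

from __future__ import annotations

import numpy as np

SECONDS_PER_MINUTE = 60.0


def px_to_um(px, pixel_size: float):
    """Length in pixels -> micrometres."""
    return np.asarray(px, dtype=float) * pixel_size


def um_to_px(um, pixel_size: float):
    """Length in micrometres -> pixels."""
    return np.asarray(um, dtype=float) / pixel_size


def area_px_to_um2(px_count, pixel_size: float):
    """Pixel count -> area in µm²."""
    return np.asarray(px_count, dtype=float) * pixel_size**2


def frames_to_seconds(frames, frame_interval: float):
    return np.asarray(frames, dtype=float) * frame_interval


def px_per_frame_to_um_per_min(disp_px, pixel_size: float, frame_interval: float):
    """Per-frame pixel displacement -> velocity in µm/min."""
    return (
        np.asarray(disp_px, dtype=float)
        * pixel_size
        / frame_interval
        * SECONDS_PER_MINUTE
    )


def um_per_min_to_px_per_frame(v_um_min, pixel_size: float, frame_interval: float):
    """Velocity in µm/min -> per-frame pixel displacement."""
    return (
        np.asarray(v_um_min, dtype=float)
        / SECONDS_PER_MINUTE
        * frame_interval
        / pixel_size
    )


def px_per_frame_to_um_per_s(disp_px, pixel_size: float, frame_interval: float):
    """Per-frame pixel displacement -> velocity in µm/s."""
    return np.asarray(disp_px, dtype=float) * pixel_size / frame_interval


def um_per_s_to_px_per_frame(v_um_s, pixel_size: float, frame_interval: float):
    return np.asarray(v_um_s, dtype=float) * frame_interval / pixel_size
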