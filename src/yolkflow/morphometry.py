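"""Whole-embryo shape and epiboly-progression morphometry.

Circularity is the classic ``4πA/P²`` (1 for a perfect circle), with the
perimeter taken as the arc length of a lightly smoothed marching-squares
contour of the silhouette: raw pixel-edge perimeters systematically
overestimate P and depress circularity, while the smoothed sub-pixel
contour converges to the true perimeter as resolution grows. Epiboly
progression is the fraction of the animal–vegetal axis covered by the
blastoderm: the scalar projection of the margin landmark onto the
pole-to-pole axis divided by the axis length. Mutant measurements are
normalized per trial to that trial's wild-type average.
"""

from __future__ import annotations

import numpy as np
from skimage import measure as _measure


def _smooth_closed_contour(contour: np.ndarray, window: int = 7) -> np.ndarray:
    """Circular moving-average of contour vertices (sub-pixel smoothing)."""
    if len(contour) <= window:
        return contour
    kernel = np.ones(window) / window
    out = np.empty_like(contour)
    for axis in range(2):
        padded = np.concatenate(
            [contour[-(window // 2):, axis], contour[:, axis], contour[: window // 2, axis]]
        )
        out[:, axis] = np.convolve(padded, kernel, mode="valid")
    return out


def circularity(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """``4πA/P²`` of a single-component silhouette.

    A is the foreground pixel count, P the arc length of the smoothed
    marching-squares contour. Values slightly above 1 can occur from
    discretization and are returned uncapped.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    n_comp = _measure.label(mask, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(f"mask must have exactly one component, found {n_comp}")
    if mask.sum() < 100:
        raise ValueError("component too small (< 100 px) for a stable perimeter")
    contours = _measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    # smoothing span grows with contour length so the staircase residual
    # vanishes as resolution increases (convergent perimeter estimate)
    window = max(5, (len(contour) // 80) | 1)
    contour = _smooth_closed_contour(contour, window)
    closed = np.vstack([contour, contour[:1]])
    perimeter_px = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
    area_px = float(mask.sum())
    # pixel_size cancels in the ratio; accepted for interface symmetry
    return 4.0 * np.pi * area_px / perimeter_px**2


def epiboly_progression(animal_pole, margin, vegetal_pole, tolerance: float = 0.02) -> float:
    """Fraction of the animal–vegetal axis covered by the margin.

    The margin landmark is projected onto the pole-to-pole axis; the
    fraction is the projection parameter, clipped only within
    ``tolerance`` outside [0, 1] (beyond that is an error).
    """
    a = np.asarray(animal_pole, dtype=float)
    v = np.asarray(vegetal_pole, dtype=float)
    m = np.asarray(margin, dtype=float)
    axis = v - a
    length2 = float(axis @ axis)
    if length2 == 0:
        raise ValueError("animal and vegetal poles coincide")
    frac = float((m - a) @ axis / length2)
    if frac < -tolerance or frac > 1 + tolerance:
        raise ValueError(
            f"margin projects at {frac:.3f}, outside [0, 1] beyond tolerance {tolerance}"
        )
    return min(max(frac, 0.0), 1.0)


def normalize_to_reference(values, reference_values) -> np.ndarray:
    """Divide each value by the arithmetic mean of the reference set
    (per-trial wild-type normalization)."""
    reference = np.asarray(reference_values, dtype=float)
    if reference.size == 0:
        raise ValueError("reference set is empty")
    ref_mean = float(reference.mean())
    if ref_mean == 0:
        raise ValueError("reference mean is zero")
    return np.asarray(values, dtype=float) / ref_mean
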