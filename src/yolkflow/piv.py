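"""Particle image velocimetry on cortical actin time-lapse movies.

Cortical actomyosin flow is estimated by windowed cross-correlation: each
interrogation window in frame *t* is compared against a slightly larger
search region in frame *t+1* using mean-subtracted normalized
cross-correlation (NCC). The displacement is the location of the
correlation maximum, optionally refined to sub-pixel precision by
three-point Gaussian peak interpolation. Vector quality is the ratio of
the primary correlation peak to the secondary peak (the maximum outside a
3×3 exclusion zone around the primary), the standard spurious-vector
criterion in PIV practice; vectors are additionally capped at a maximum
plausible flow speed.

Orientation convention: images are row-major with the margin at the top,
so "up" (animal direction) is decreasing row index. Vector angles are
measured as ``atan2(-dy, dx)`` so that up maps to 90°.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _stats
from skimage.feature import match_template

from .io import CalibratedStack

_EPS = 1e-12


class PivParameterError(ValueError):
    """Interrogation-window geometry incompatible with the image."""


@dataclass
class PivParams:
    """Interrogation and filtering parameters.

    ``window_um`` is the interrogation window edge length in µm (default
    14.8, a region-of-interest size suited to the yolk cortex at 60×);
    it is converted to pixels per run and rounded to the nearest even
    integer. ``s2n_threshold`` (default 1.0) and ``speed_cap`` (default
    1.0 µm/min, the upper end of reported cortical actin flow speeds)
    drive :func:`filter_vectors`.
    """

    window_um: float = 14.8
    overlap_fraction: float = 0.5
    search_margin_px: int = 8
    s2n_threshold: float = 1.0
    speed_cap: float = 1.0
    subpixel: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 1):
            raise PivParameterError("overlap_fraction must be in [0, 1)")
        if self.speed_cap <= 0:
            raise PivParameterError("speed_cap must be > 0 µm/min")
        if self.search_margin_px < 1:
            raise PivParameterError("search_margin_px must be >= 1")

    def window_px(self, stack: CalibratedStack) -> int:
        """Window edge in pixels: window_um converted, rounded to even."""
        w = int(round(float(stack.um_to_px(self.window_um)) / 2.0)) * 2
        if w < 8:
            raise PivParameterError(
                f"window of {self.window_um} µm is {w} px at this calibration; minimum is 8 px"
            )
        return w


@dataclass
class VectorField:
    """Per-window displacement vectors for one consecutive frame pair.

    ``rows``/``cols`` are window-center positions (px); ``dx``/``dy`` the
    per-frame displacements (px, dx along columns, dy along rows, row-down
    positive); ``vx``/``vy`` the same in µm/min; ``s2n`` the
    peak-to-second-peak ratio; ``valid`` the filtering flag. Invalid
    vectors keep their raw values but are excluded from every summary.
    """

    rows: np.ndarray
    cols: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    s2n: np.ndarray
    valid: np.ndarray
    frame_pair: int

    @property
    def n_vectors(self) -> int:
        return self.dx.size

    def speeds_um_min(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)


@dataclass
class DirectionalSummary:
    """Pooled direction/speed summary of valid vectors.

    Quadrants are half-open 90° sectors centred on the image axes:
    right [-45°, 45°), up [45°, 135°), left [135°, 225°), down
    [225°, 315°), with angles measured as atan2(-dy, dx).
    """

    quadrant_counts: dict
    quadrant_fractions: dict
    rose_bin_edges_deg: np.ndarray
    rose_counts: np.ndarray
    n_valid: int
    mean_speed_um_min: float


@dataclass
class TestResult:
    """Outcome of a hypothesis test, tails recorded verbatim."""

    name: str
    statistic: float
    p_value: float
    tails: str
    df: Optional[float] = None
    group_sizes: Optional[tuple] = None


QUADRANT_ORDER = ("up", "down", "left", "right")


def _gauss_interp(c_m: float, c_0: float, c_p: float) -> float:
    """Three-point Gaussian (log-parabolic) sub-pixel peak offset.

    Falls back to parabolic interpolation when a neighbour is
    non-positive (log undefined), and to 0 when the peak is flat.
    """
    if c_m > 0 and c_0 > 0 and c_p > 0:
        lm, l0, lp = np.log(c_m), np.log(c_0), np.log(c_p)
        denom = 2.0 * (lm + lp - 2.0 * l0)
        if denom < 0:
            return float((lm - lp) / denom)
    denom = 2.0 * (c_m + c_p - 2.0 * c_0)
    if denom < 0:
        return float((c_m - c_p) / denom)
    return 0.0


def _window_grid(extent: int, window: int, step: int, margin: int) -> np.ndarray:
    """Window start offsets, inset by the search margin on both sides."""
    last = extent - margin - window
    if last < margin:
        return np.array([], dtype=int)
    return np.arange(margin, last + 1, step, dtype=int)


def compute_piv(stack: CalibratedStack, params: PivParams) -> list[VectorField]:
    """Windowed NCC flow estimation over every consecutive frame pair.

    For each tiled interrogation window the NCC between the window in
    frame *t* and the ``window ± search_margin`` region of frame *t+1* is
    computed; the displacement is the argmax, refined by three-point
    Gaussian interpolation per axis when ``params.subpixel`` is on.
    Constant (zero-variance) windows are flagged invalid with s2n 0.
    """
    if stack.n_frames < 2:
        raise PivParameterError("PIV needs at least 2 frames")
    win = params.window_px(stack)
    margin = params.search_margin_px
    h, w = stack.frame_shape
    if win + 2 * margin > h or win + 2 * margin > w:
        raise PivParameterError(
            f"window {win}px + 2x{margin}px search margin exceeds frame {h}x{w}"
        )
    step = max(1, int(round(win * (1.0 - params.overlap_fraction))))
    row_starts = _window_grid(h, win, step, margin)
    col_starts = _window_grid(w, win, step, margin)
    if row_starts.size == 0 or col_starts.size == 0:
        raise PivParameterError("no interrogation windows fit inside the frame")

    frames = stack.frames.astype(float, copy=False)
    fields: list[VectorField] = []
    for t in range(stack.n_frames - 1):
        f0, f1 = frames[t], frames[t + 1]
        n = row_starts.size * col_starts.size
        rows = np.empty(n)
        cols = np.empty(n)
        dxs = np.empty(n)
        dys = np.empty(n)
        s2ns = np.empty(n)
        valid = np.ones(n, dtype=bool)
        k = 0
        for r0 in row_starts:
            for c0 in col_starts:
                template = f0[r0 : r0 + win, c0 : c0 + win]
                rows[k] = r0 + (win - 1) / 2.0
                cols[k] = c0 + (win - 1) / 2.0
                if template.std() < _EPS:
                    dxs[k] = dys[k] = 0.0
                    s2ns[k] = 0.0
                    valid[k] = False
                    k += 1
                    continue
                search = f1[r0 - margin : r0 + win + margin, c0 - margin : c0 + win + margin]
                if search.std() < _EPS:
                    dxs[k] = dys[k] = 0.0
                    s2ns[k] = 0.0
                    valid[k] = False
                    k += 1
                    continue
                cc = match_template(search, template)
                cc = np.nan_to_num(cc, nan=-1.0, posinf=-1.0, neginf=-1.0)
                pi, pj = np.unravel_index(np.argmax(cc), cc.shape)
                peak = cc[pi, pj]
                dy = float(pi - margin)
                dx = float(pj - margin)
                if params.subpixel:
                    if 0 < pi < cc.shape[0] - 1:
                        dy += _gauss_interp(cc[pi - 1, pj], peak, cc[pi + 1, pj])
                    if 0 < pj < cc.shape[1] - 1:
                        dx += _gauss_interp(cc[pi, pj - 1], peak, cc[pi, pj + 1])
                # secondary peak outside a 3x3 exclusion zone
                masked = cc.copy()
                masked[max(0, pi - 1) : pi + 2, max(0, pj - 1) : pj + 2] = -np.inf
                second = float(masked.max()) if np.isfinite(masked).any() else 0.0
                s2ns[k] = float(peak / max(second, _EPS)) if second > 0 else np.inf
                dxs[k] = dx
                dys[k] = dy
                k += 1
        vx = stack.px_per_frame_to_um_per_min(dxs)
        vy = stack.px_per_frame_to_um_per_min(dys)
        fields.append(
            VectorField(
                rows=rows, cols=cols, dx=dxs, dy=dys, vx=vx, vy=vy,
                s2n=s2ns, valid=valid, frame_pair=t,
            )
        )
    return fields


def filter_vectors(fld: VectorField, params: PivParams) -> VectorField:
    """Flag spurious vectors; values are untouched.

    A vector stays valid only when its peak-to-second-peak ratio exceeds
    ``s2n_threshold`` and its speed does not exceed ``speed_cap`` µm/min
    (abnormally fast vectors are removed outright).
    """
    speeds = fld.speeds_um_min()
    valid = fld.valid & (fld.s2n > params.s2n_threshold) & (speeds <= params.speed_cap)
    return replace(fld, valid=valid)


def vector_angles_deg(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Angle of each vector in degrees, in [0, 360); up (−dy) is 90°."""
    return np.degrees(np.arctan2(-np.asarray(dy), np.asarray(dx))) % 360.0


def quadrant_of(angles_deg: np.ndarray) -> np.ndarray:
    """Quadrant index 0=right, 1=up, 2=left, 3=down (half-open sectors)."""
    return (((np.asarray(angles_deg) + 45.0) % 360.0) // 90.0).astype(int)


def directional_summary(
    fields: Sequence[VectorField], rose_bins: int = 36
) -> DirectionalSummary:
    """Pool valid vectors across frame pairs into a direction summary."""
    dx = np.concatenate([f.dx[f.valid] for f in fields]) if fields else np.array([])
    dy = np.concatenate([f.dy[f.valid] for f in fields]) if fields else np.array([])
    speeds = (
        np.concatenate([f.speeds_um_min()[f.valid] for f in fields])
        if fields
        else np.array([])
    )
    n = dx.size
    if n == 0:
        raise ValueError("no valid vectors to summarize")
    angles = vector_angles_deg(dx, dy)
    quad_idx = quadrant_of(angles)
    names_by_idx = {0: "right", 1: "up", 2: "left", 3: "down"}
    counts = {name: 0 for name in QUADRANT_ORDER}
    for idx in range(4):
        counts[names_by_idx[idx]] = int(np.sum(quad_idx == idx))
    fractions = {k: v / n for k, v in counts.items()}
    edges = np.linspace(0.0, 360.0, rose_bins + 1)
    rose_counts, _ = np.histogram(angles, bins=edges)
    return DirectionalSummary(
        quadrant_counts=counts,
        quadrant_fractions=fractions,
        rose_bin_edges_deg=edges,
        rose_counts=rose_counts,
        n_valid=n,
        mean_speed_um_min=float(speeds.mean()),
    )


def compare_quadrants(observed, reference) -> TestResult:
    """Pearson χ² goodness-of-fit of quadrant counts, upper-tail p.

    ``observed`` are nonnegative counts; ``reference`` the expected
    proportions (all > 0, summing to 1). df = k−1.
    """
    observed = np.asarray(observed, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if observed.shape != reference.shape:
        raise ValueError(
            f"observed ({observed.size}) and reference ({reference.size}) lengths differ"
        )
    if np.any(observed < 0) or observed.sum() <= 0:
        raise ValueError("observed counts must be nonnegative with positive total")
    if np.any(reference <= 0):
        raise ValueError("every reference proportion must be > 0")
    if not np.isclose(reference.sum(), 1.0):
        raise ValueError("reference proportions must sum to 1")
    n_total = observed.sum()
    expected = n_total * reference
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    df = observed.size - 1
    p = float(_stats.chi2.sf(statistic, df))
    return TestResult(
        name="chi_square_gof",
        statistic=statistic,
        p_value=p,
        tails="one",
        df=float(df),
        group_sizes=(int(n_total),),
    )
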