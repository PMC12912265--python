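"""Time-resolved intensity kinetics: FRAP, ablation recoil, accumulation.

FRAP recovery is modelled as a single exponential
``N(t) = m·(1 − exp(−t/τ))`` on the bleach-depth-normalized trace, the
standard description for cortical actin turnover; the reported half-time
is ``τ·ln 2`` and the mobile fraction is the plateau ``m``. Ablation
recoil is summarized by the initial opening velocity of the cut — the
slope of gap width versus time over a short early window, a tension
proxy. Fluorescence accumulation is an ordinary least-squares slope of a
first-frame-normalized intensity series, in per-minute units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats as _stats

from .io import CalibratedStack, Roi

LN2 = float(np.log(2.0))


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or produced invalid parameters."""


@dataclass
class RecoveryCurve:
    """Bleach-depth-normalized FRAP trace.

    ``times`` are seconds with 0 at the bleach frame; ``values`` are
    normalized so 0 is the bleach floor and 1 full recovery to the
    pre-bleach level. The raw normalization constants are retained.
    """

    times: np.ndarray
    values: np.ndarray
    n_pre: int
    bleach_index: int
    prebleach_mean: float
    first_postbleach: float


@dataclass
class FrapFit:
    f0: float
    f_inf: float
    tau: float
    half_time: float
    mobile_fraction: float
    residual_rms: float


@dataclass
class RecoilSeries:
    """Post-cut gap widths over time; t = 0 at the first post-cut frame."""

    times: np.ndarray
    widths_um: np.ndarray
    velocity_um_s: Optional[float] = None
    velocity_se: Optional[float] = None
    fit_frames: Optional[int] = None


@dataclass
class IntensitySeries:
    times_s: np.ndarray
    values: np.ndarray
    normalization: str  # none | first-frame | blastoderm-roi
    slope_per_min: Optional[float] = None
    slope_se: Optional[float] = None


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def normalize_frap(raw, bleach_index: int, frame_interval: float) -> RecoveryCurve:
    """Full-scale (bleach-depth) normalization of a raw FRAP trace.

    ``N(t) = (F(t) − F_bleach) / (F_pre − F_bleach)`` with ``F_pre`` the
    mean of the pre-bleach frames and ``F_bleach`` the first post-bleach
    value, so incomplete bleaching is absorbed into the denominator.
    """
    raw = np.asarray(raw, dtype=float)
    if bleach_index < 2:
        raise ValueError("need at least 2 pre-bleach frames")
    if bleach_index >= raw.size:
        raise ValueError("bleach_index beyond end of trace")
    f_pre = float(raw[:bleach_index].mean())
    f_bleach = float(raw[bleach_index])
    depth = f_pre - f_bleach
    if depth <= 0:
        raise ValueError(
            f"no bleach detected: prebleach mean {f_pre:.6g} <= first postbleach {f_bleach:.6g}"
        )
    from . import units

    post = raw[bleach_index:]
    times = np.asarray(units.frames_to_seconds(np.arange(post.size), frame_interval))
    values = (post - f_bleach) / depth
    return RecoveryCurve(
        times=times,
        values=values,
        n_pre=bleach_index,
        bleach_index=bleach_index,
        prebleach_mean=f_pre,
        first_postbleach=f_bleach,
    )


def _recovery_model(t, m, tau):
    return m * (1.0 - np.exp(-t / tau))


def fit_recovery(curve: RecoveryCurve, max_iter: int = 10_000) -> FrapFit:
    """Least-squares single-exponential fit of a normalized recovery curve.

    Initialized with ``m₀`` = last observed value and ``τ₀`` = time to
    reach half of the final observed value; converges to 1e-8 on the
    parameters. Degenerate (flat, non-recovering) curves raise
    :class:`FitError`.
    """
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.values, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 post-bleach points to fit")
    m0 = float(y[-1])
    if m0 <= 0:
        raise FitError(f"no recovery to fit: final normalized value {m0:.4g} <= 0")
    above = np.nonzero(y >= 0.5 * m0)[0]
    tau0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[-1] / 4 + 1e-6)
    try:
        popt, pcov = optimize.curve_fit(
            _recovery_model,
            t,
            y,
            p0=(m0, tau0),
            maxfev=max_iter,
            xtol=1e-8,
            ftol=1e-8,
        )
    except RuntimeError as exc:
        raise FitError(
            f"recovery fit did not converge from m0={m0:.4g}, tau0={tau0:.4g}: {exc}"
        ) from exc
    m_hat, tau_hat = (float(v) for v in popt)
    if tau_hat <= 0:
        raise FitError(f"fitted tau {tau_hat:.4g} s is not positive")
    resid = y - _recovery_model(t, m_hat, tau_hat)
    return FrapFit(
        f0=0.0,
        f_inf=m_hat,
        tau=tau_hat,
        half_time=tau_hat * LN2,
        mobile_fraction=m_hat,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


# ---------------------------------------------------------------------------
# Ablation recoil
# ---------------------------------------------------------------------------

def measure_gap_width(
    stack: CalibratedStack,
    strip_roi: Roi,
    intensity_threshold_fraction: float = 0.5,
    cut_index: int = 1,
) -> RecoilSeries:
    """Track the opening of a horizontal ablation cut over time.

    The strip roi crosses the cut perpendicular to the cut line; each
    frame's profile is the intensity averaged across the strip's short
    axis. The gap is the longest contiguous run of profile values below
    ``intensity_threshold_fraction`` × the median pre-cut profile level,
    converted to µm. ``cut_index`` is the first post-cut frame; frames
    before it provide the baseline.
    """
    if cut_index < 1:
        raise ValueError("need at least one pre-cut frame for the baseline")
    if cut_index >= stack.n_frames:
        raise ValueError("no post-cut frames")
    r0, c0, h, w = strip_roi.bounding_box(stack.frame_shape)
    sub = stack.frames[:, r0 : r0 + h, c0 : c0 + w].astype(float)
    long_axis = 1 if h >= w else 2  # average across the SHORT axis
    profiles = sub.mean(axis=(3 - long_axis))  # (t, profile_len)
    baseline = float(np.median(profiles[:cut_index]))
    if baseline <= 0:
        raise ValueError("pre-cut baseline level is not positive")
    thresh = intensity_threshold_fraction * baseline
    widths_px = np.array([_gap_width_px(p, thresh) for p in profiles[cut_index:]])
    widths_um = np.asarray(stack.px_to_um(widths_px), dtype=float)
    times = np.asarray(
        stack.frames_to_seconds(np.arange(widths_um.size)), dtype=float
    )
    return RecoilSeries(times=times, widths_um=widths_um)


def _gap_width_px(profile: np.ndarray, thresh: float) -> float:
    """Width of the longest sub-threshold run, with the two bounding
    threshold crossings located by linear interpolation (sub-pixel)."""
    below = profile < thresh
    best_len = run = 0
    best_end = -1
    for i, v in enumerate(below):
        run = run + 1 if v else 0
        if run > best_len:
            best_len, best_end = run, i
    if best_len == 0:
        return 0.0
    i0 = best_end - best_len + 1
    i1 = best_end
    left = float(i0) - 0.5
    if i0 > 0 and profile[i0 - 1] != profile[i0]:
        left = (i0 - 1) + (profile[i0 - 1] - thresh) / (profile[i0 - 1] - profile[i0])
    right = float(i1) + 0.5
    if i1 < profile.size - 1 and profile[i1 + 1] != profile[i1]:
        right = i1 + (thresh - profile[i1]) / (profile[i1 + 1] - profile[i1])
    return max(right - left, 0.0)


def recoil_velocity(series: RecoilSeries, fit_frames: int = 5) -> RecoilSeries:
    """Initial recoil velocity: OLS slope of width vs time over the first
    ``fit_frames`` post-cut points, with its standard error (µm/s)."""
    if fit_frames < 2:
        raise ValueError("fit_frames must be >= 2")
    if fit_frames > series.times.size:
        raise ValueError(
            f"fit_frames {fit_frames} exceeds series length {series.times.size}"
        )
    t = series.times[:fit_frames]
    y = series.widths_um[:fit_frames]
    res = _stats.linregress(t, y)
    return RecoilSeries(
        times=series.times,
        widths_um=series.widths_um,
        velocity_um_s=float(res.slope),
        velocity_se=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        fit_frames=fit_frames,
    )


# ---------------------------------------------------------------------------
# Intensity series / accumulation slope
# ---------------------------------------------------------------------------

def intensity_series(
    stack: CalibratedStack,
    roi: Roi,
    normalization: str = "none",
    reference_roi: Optional[Roi] = None,
) -> IntensitySeries:
    """Mean roi intensity per frame with the chosen normalization.

    ``first-frame`` divides the whole series by its frame-0 value (the
    accumulation convention); ``blastoderm-roi`` divides each frame's roi
    mean by the same frame's reference-roi mean, which cancels global
    per-frame intensity changes such as photobleaching.
    """
    if normalization not in ("none", "first-frame", "blastoderm-roi"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if (normalization == "blastoderm-roi") != (reference_roi is not None):
        raise ValueError("reference_roi is required iff normalization='blastoderm-roi'")
    member = roi.to_mask(stack.frame_shape)
    if not member.any():
        raise ValueError("roi selects no pixels")
    vals = stack.frames[:, member].astype(float).mean(axis=1)
    if normalization == "first-frame":
        if vals[0] == 0:
            raise ValueError("frame-0 roi mean is zero; cannot normalize")
        vals = vals / vals[0]
    elif normalization == "blastoderm-roi":
        ref_member = reference_roi.to_mask(stack.frame_shape)
        if not ref_member.any():
            raise ValueError("reference roi selects no pixels")
        ref = stack.frames[:, ref_member].astype(float).mean(axis=1)
        if np.any(ref == 0):
            raise ValueError("reference roi mean is zero in at least one frame")
        vals = vals / ref
    return IntensitySeries(
        times_s=stack.times_s(), values=vals, normalization=normalization
    )


def accumulation_slope(series: IntensitySeries) -> IntensitySeries:
    """OLS slope of a first-frame-normalized intensity series, per minute."""
    if series.normalization != "first-frame":
        raise ValueError(
            "accumulation slope requires a first-frame-normalized series, "
            f"got normalization={series.normalization!r}"
        )
    if series.times_s.size < 3:
        raise ValueError("need at least 3 time points")
    t_min = series.times_s / 60.0
    res = _stats.linregress(t_min, series.values)
    return IntensitySeries(
        times_s=series.times_s,
        values=series.values,
        normalization=series.normalization,
        slope_per_min=float(res.slope),
        slope_se=float(res.stderr),
    )
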