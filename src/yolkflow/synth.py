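"""Synthetic calibrated time-lapse stacks with exported ground truth.

Every imaging modality the pipeline quantifies has a generator here:
advected punctate actin texture with a programmed velocity field, FRAP
recovery traces with incomplete bleaching, a post-ablation gap opening
with saturating kinetics, disk-shaped endocytic puncta of controlled
area, linearly moving comets, and elliptical embryo silhouettes. Each
generator returns its artifact together with a :class:`GroundTruth`
sidecar, and writes both atomically when given an output path.

Imaging noise follows the standard fluorescence-camera model: Poisson
shot noise on the noiseless image scaled to a stated photon budget,
followed by additive Gaussian read noise. Both stages are optional.
Spots are rendered analytically (Gaussian evaluated at pixel centres at
sub-pixel positions) rather than by integer-shift resampling, so the
texture carries true sub-pixel motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import units
from .io import CalibratedStack, write_stack


@dataclass
class GroundTruth:
    """Sidecar record of a generator's true parameters and fields."""

    kind: str
    data: dict

    def save(self, path) -> Path:
        path = Path(path)

        def _convert(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: _convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_convert(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        path.write_text(json.dumps({"kind": self.kind, "data": _convert(self.data)}, indent=2))
        return path

    @classmethod
    def load(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(kind=payload["kind"], data=payload["data"])


@dataclass
class NoiseModel:
    """Poisson shot noise at ``photon_budget`` counts per unit intensity
    (None disables it) plus Gaussian read noise of ``gauss_sigma`` counts."""

    photon_budget: Optional[float] = None
    gauss_sigma: float = 0.0

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(image, dtype=float)
        if self.photon_budget is not None:
            out = rng.poisson(np.clip(out, 0, None) * self.photon_budget).astype(float)
            out /= self.photon_budget
        if self.gauss_sigma > 0:
            out = out + rng.normal(0.0, self.gauss_sigma, size=out.shape)
        return out


NO_NOISE = NoiseModel()


# ---------------------------------------------------------------------------
# Gaussian spot rendering
# ---------------------------------------------------------------------------

def render_spots(
    shape: tuple[int, int],
    positions: np.ndarray,
    sigma_px: float,
    amplitudes=1.0,
    periodic: bool = False,
) -> np.ndarray:
    """Render Gaussian spots at sub-pixel ``(row, col)`` positions.

    Each spot is the analytic Gaussian evaluated at pixel centres within
    ±4σ. With ``periodic`` on, spots near an edge also contribute their
    wrapped copies, so a torus-advected texture has stationary statistics.
    """
    h, w = shape
    img = np.zeros((h, w), dtype=float)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        return img
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(positions),))
    reach = max(1, int(np.ceil(4.0 * sigma_px)))
    offsets = [(0.0, 0.0)]
    if periodic:
        offsets = [(dr * h, dc * w) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
    for (r, c), amp in zip(positions, amplitudes):
        for orow, ocol in offsets:
            rr, cc = r + orow, c + ocol
            r_lo, r_hi = int(np.floor(rr - reach)), int(np.ceil(rr + reach)) + 1
            c_lo, c_hi = int(np.floor(cc - reach)), int(np.ceil(cc + reach)) + 1
            r_lo, r_hi = max(r_lo, 0), min(r_hi, h)
            c_lo, c_hi = max(c_lo, 0), min(c_hi, w)
            if r_lo >= r_hi or c_lo >= c_hi:
                continue
            ys = np.arange(r_lo, r_hi)[:, None] - rr
            xs = np.arange(c_lo, c_hi)[None, :] - cc
            img[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(
                -(ys**2 + xs**2) / (2.0 * sigma_px**2)
            )
    return img


# ---------------------------------------------------------------------------
# Flow stacks
# ---------------------------------------------------------------------------

@dataclass
class FlowScenario:
    """Programmed cortical-flow field for the puncta texture.

    ``kind`` is ``uniform`` (constant ``(vx, vy)`` µm/min; vy positive is
    downward/vegetal, so upward margin-directed flow has vy < 0),
    ``vertical_gradient`` (upward speed varying linearly from
    ``top_speed`` at the first row to ``bottom_speed`` at the last), or
    ``mixture`` (each spatial block of ``block_um`` is assigned one of
    up/down/left/right with the given fractions and per-class speed; a
    locally coherent patchwork, so windowed correlation can resolve each
    block's direction). Defaults mirror the acquisition they emulate:
    0.5 s/frame movies of sub-µm/min cortical flow.
    """

    kind: str = "uniform"
    vx: float = 0.0
    vy: float = -0.5
    top_speed: float = 0.5
    bottom_speed: float = 0.0
    fractions: Optional[dict] = None
    class_speed: float = 0.5
    block_um: float = 14.8
    block_offset_px: int = 0
    puncta_density: float = 0.5  # puncta per µm²; dense, near-continuous cortex texture
    puncta_sigma: float = 0.35  # PSF sigma, µm
    n_frames: int = 10
    noise: NoiseModel = field(default_factory=lambda: NO_NOISE)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "vertical_gradient", "mixture"):
            raise ValueError(f"unknown flow scenario kind {self.kind!r}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.puncta_density <= 0:
            raise ValueError("puncta_density must be > 0")
        if self.kind == "mixture" and self.fractions is None:
            self.fractions = {"up": 0.7, "down": 0.3}


_DIRECTIONS = {  # (drow, dcol) unit vectors; up = decreasing row
    "up": (-1.0, 0.0),
    "down": (1.0, 0.0),
    "left": (0.0, -1.0),
    "right": (0.0, 1.0),
}


def _velocity_field_um_min(scn: FlowScenario, shape, pixel_size, rng):
    """Return per-position velocity lookup ``(rows, cols) -> (vy, vx)`` in
    µm/min, plus mixture block assignments when relevant."""
    h, w = shape
    if scn.kind == "uniform":
        def lookup(r, c):
            return np.full_like(r, scn.vy, dtype=float), np.full_like(r, scn.vx, dtype=float)
        return lookup, None
    if scn.kind == "vertical_gradient":
        def lookup(r, c):
            frac = np.asarray(r, dtype=float) / max(h - 1, 1)
            speed = scn.top_speed + (scn.bottom_speed - scn.top_speed) * frac
            return -speed, np.zeros_like(speed)  # upward flow
        return lookup, None
    # mixture: one direction class per block of block_um; the block grid may
    # be offset so blocks align with the PIV interrogation windows
    block_px = max(1, int(round(units.um_to_px(scn.block_um, pixel_size))))
    off = scn.block_offset_px
    n_br = int(np.ceil((h + off) / block_px)) + 1
    n_bc = int(np.ceil((w + off) / block_px)) + 1
    names = list(scn.fractions.keys())
    probs = np.asarray([scn.fractions[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    choice = rng.choice(len(names), size=(n_br, n_bc), p=probs)
    vy_block = np.empty((n_br, n_bc))
    vx_block = np.empty((n_br, n_bc))
    for idx, name in enumerate(names):
        dr, dc = _DIRECTIONS[name]
        vy_block[choice == idx] = dr * scn.class_speed
        vx_block[choice == idx] = dc * scn.class_speed

    def lookup(r, c):
        br = np.clip(((np.asarray(r) - off) // block_px).astype(int) + 1, 0, n_br - 1)
        bc = np.clip(((np.asarray(c) - off) // block_px).astype(int) + 1, 0, n_bc - 1)
        return vy_block[br, bc], vx_block[br, bc]

    blocks = {
        "block_px": block_px,
        "block_offset_px": off,
        "class_names": names,
        "choice": choice,
        "vy_block": vy_block,
        "vx_block": vx_block,
    }
    return lookup, blocks


def make_flow_stack(
    scenario: FlowScenario,
    pixel_size: float,
    frame_interval: float = 0.5,
    shape: tuple[int, int] = (256, 256),
    out_dir=None,
) -> tuple[CalibratedStack, GroundTruth]:
    """Advect a punctate texture by the scenario's velocity field.

    Puncta positions move sub-pixel amounts each frame and wrap
    periodically at the boundaries so the density stays stationary.
    The ground truth records the scenario and the true velocity field
    sampled on any grid via :func:`true_field_at`.
    """
    rng = np.random.default_rng(scenario.seed)
    h, w = shape
    area_um2 = float(units.area_px_to_um2(h * w, pixel_size))
    n_puncta = max(1, int(round(scenario.puncta_density * area_um2)))
    sigma_px = float(units.um_to_px(scenario.puncta_sigma, pixel_size))
    positions = np.column_stack([rng.uniform(0, h, n_puncta), rng.uniform(0, w, n_puncta)])
    lookup, blocks = _velocity_field_um_min(scenario, shape, pixel_size, rng)

    # warn (via ValueError per contract) if the per-frame displacement is
    # beyond what the default window/search geometry can recover
    max_speed = {
        "uniform": float(np.hypot(scenario.vx, scenario.vy)),
        "vertical_gradient": float(max(abs(scenario.top_speed), abs(scenario.bottom_speed))),
        "mixture": float(scenario.class_speed),
    }[scenario.kind]
    max_disp = float(
        units.um_per_min_to_px_per_frame(max_speed, pixel_size, frame_interval)
    )
    import warnings as _warnings

    if max_disp > 8:
        _warnings.warn(
            f"per-frame displacement {max_disp:.1f} px exceeds the default search "
            "margin; flow will not be recoverable by PIV at these settings",
            stacklevel=2,
        )

    frames = np.empty((scenario.n_frames, h, w), dtype=float)
    pos = positions.copy()
    for t in range(scenario.n_frames):
        frames[t] = scenario.noise.apply(
            render_spots(shape, pos, sigma_px, periodic=True), rng
        )
        vy, vx = lookup(pos[:, 0], pos[:, 1])
        pos[:, 0] = (pos[:, 0] + units.um_per_min_to_px_per_frame(vy, pixel_size, frame_interval)) % h
        pos[:, 1] = (pos[:, 1] + units.um_per_min_to_px_per_frame(vx, pixel_size, frame_interval)) % w

    stack = CalibratedStack(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel_label="synthetic actin puncta",
    )
    gt_data: dict = {
        "scenario_kind": scenario.kind,
        "pixel_size": pixel_size,
        "frame_interval": frame_interval,
        "n_puncta": n_puncta,
        "uniform_vx": scenario.vx,
        "uniform_vy": scenario.vy,
        "top_speed": scenario.top_speed,
        "bottom_speed": scenario.bottom_speed,
        "class_speed": scenario.class_speed,
        "seed": scenario.seed,
    }
    if blocks is not None:
        gt_data["mixture_blocks"] = {
            "block_px": blocks["block_px"],
            "block_offset_px": blocks["block_offset_px"],
            "class_names": blocks["class_names"],
            "choice": blocks["choice"],
        }
        gt_data["mixture_fractions"] = scenario.fractions
    gt = GroundTruth(kind="flow", data=gt_data)
    if out_dir is not None:
        _save_pair(stack, gt, out_dir, "flow")
    return stack, gt


def true_field_at(gt: GroundTruth, rows, cols) -> tuple[np.ndarray, np.ndarray]:
    """Sample the true velocity field (vy, vx in µm/min) at pixel positions
    (e.g. the PIV window centres)."""
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    d = gt.data
    if d["scenario_kind"] == "uniform":
        return (
            np.full_like(rows, d["uniform_vy"], dtype=float),
            np.full_like(rows, d["uniform_vx"], dtype=float),
        )
    if d["scenario_kind"] == "vertical_gradient":
        raise ValueError("gradient field sampling requires the image height; "
                         "use the scenario parameters directly")
    blocks = d["mixture_blocks"]
    choice = np.asarray(blocks["choice"])
    block_px = blocks["block_px"]
    off = blocks.get("block_offset_px", 0)
    names = blocks["class_names"]
    br = np.clip(((rows - off) // block_px).astype(int) + 1, 0, choice.shape[0] - 1)
    bc = np.clip(((cols - off) // block_px).astype(int) + 1, 0, choice.shape[1] - 1)
    vy = np.empty_like(rows)
    vx = np.empty_like(rows)
    for idx, name in enumerate(names):
        sel = choice[br, bc] == idx
        dr, dc = _DIRECTIONS[name]
        vy[sel] = dr * d["class_speed"]
        vx[sel] = dc * d["class_speed"]
    return vy, vx


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

def make_frap_trace(
    tau: float,
    f_pre: float = 1.0,
    f_bleach: float = 0.3,
    f_inf: float = 0.9,
    n_pre: int = 10,
    n_post: int = 120,
    dt: float = 0.5,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Single-exponential FRAP recovery trace with incomplete bleaching.

    The trace sits at ``f_pre`` for ``n_pre`` frames, drops to
    ``f_bleach`` at the bleach frame, and recovers as
    ``F(t) = f_inf − (f_inf − f_bleach)·exp(−t/τ)`` toward a plateau
    below the pre-bleach level (bleaching is rarely complete with weak
    stimulation). Gaussian noise of ``noise_sigma`` is added throughout.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if not (f_bleach < f_inf <= f_pre):
        raise ValueError(
            f"need f_bleach < f_inf <= f_pre, got {f_bleach}, {f_inf}, {f_pre}"
        )
    rng = np.random.default_rng(seed)
    t_post = np.arange(n_post) * dt
    post = f_inf - (f_inf - f_bleach) * np.exp(-t_post / tau)
    trace = np.concatenate([np.full(n_pre, f_pre, dtype=float), post])
    if noise_sigma > 0:
        trace = trace + rng.normal(0.0, noise_sigma, size=trace.size)
    gt = GroundTruth(
        kind="frap",
        data={
            "tau": tau,
            "f_pre": f_pre,
            "f_bleach": f_bleach,
            "f_inf": f_inf,
            "n_pre": n_pre,
            "dt": dt,
            "noise_sigma": noise_sigma,
            "seed": seed,
        },
    )
    return trace, gt


# ---------------------------------------------------------------------------
# Ablation stacks
# ---------------------------------------------------------------------------

def make_ablation_stack(
    w_inf: float,
    tau_r: float,
    n_frames: int = 20,
    dt: float = 0.1,
    pixel_size: float = 0.1,
    shape: tuple[int, int] = (200, 64),
    n_pre: int = 2,
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
) -> tuple[CalibratedStack, GroundTruth]:
    """Bright cortical strip with a horizontal cut opening along rows.

    From the ablation frame on, a dark gap of width
    ``w(t) = w_inf·(1 − exp(−t/τ_r))`` (µm) grows about the centre row,
    the saturating recoil kinetics of a cut under tension; the true
    initial recoil velocity is ``w_inf/τ_r``. Gap edges are rendered with
    sub-pixel coverage so the half-maximum crossing sits at the true edge.
    ``n_frames`` counts post-cut frames; ``n_pre`` uncut baseline frames
    precede them.
    """
    if w_inf <= 0 or tau_r <= 0:
        raise ValueError("w_inf and tau_r must be > 0")
    h, w = shape
    if units.um_to_px(w_inf, pixel_size) >= h:
        raise ValueError("asymptotic gap width exceeds the image height")
    rng = np.random.default_rng(seed)
    centre = (h - 1) / 2.0
    rows = np.arange(h, dtype=float)
    frames = np.empty((n_pre + n_frames, h, w), dtype=float)
    widths_um = []
    for k in range(n_pre + n_frames):
        if k < n_pre:
            gap_um = 0.0
        else:
            t = (k - n_pre) * dt
            gap_um = w_inf * (1.0 - np.exp(-t / tau_r))
        widths_um.append(gap_um)
        half_px = float(units.um_to_px(gap_um, pixel_size)) / 2.0
        # fractional coverage of each pixel row by the bright strip
        dist = np.abs(rows - centre)
        coverage = np.clip(dist - half_px + 0.5, 0.0, 1.0)
        frame = np.repeat(coverage[:, None], w, axis=1)
        frames[k] = noise.apply(frame, rng)
    stack = CalibratedStack(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=dt,
        channel_label="synthetic ablation",
    )
    gt = GroundTruth(
        kind="ablation",
        data={
            "w_inf": w_inf,
            "tau_r": tau_r,
            "initial_recoil_velocity": w_inf / tau_r,
            "n_pre": n_pre,
            "dt": dt,
            "pixel_size": pixel_size,
            "widths_um": np.asarray(widths_um),
            "seed": seed,
        },
    )
    return stack, gt


# ---------------------------------------------------------------------------
# Endocytic puncta images
# ---------------------------------------------------------------------------

def make_puncta_image(
    n_in_band: int,
    n_oversize: int = 0,
    n_undersize: int = 0,
    area_band: tuple[float, float] = (0.2, 2.0),
    pixel_size: float = 0.1,
    shape: tuple[int, int] = (256, 256),
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
    foreground: float = 1.0,
    background: float = 0.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Uniform-intensity disks on a constant background.

    Disk areas are drawn strictly inside, above or below ``area_band``
    (µm²) for the three classes; the recorded ground-truth area of each
    disk is its rasterized pixel count × pixel_size², the area a
    connected-component counter should measure. Placement is
    rejection-sampled so disks never touch.
    """
    lo, hi = area_band
    if lo <= 0 or hi <= lo:
        raise ValueError("area_band must satisfy 0 < lo < hi")
    rng = np.random.default_rng(seed)
    h, w = shape
    span = hi - lo
    specs: list[tuple[str, float]] = []
    for _ in range(n_in_band):
        specs.append(("in_band", rng.uniform(lo + 0.15 * span, hi - 0.15 * span)))
    for _ in range(n_oversize):
        specs.append(("oversize", rng.uniform(hi * 1.5, hi * 3.0)))
    for _ in range(n_undersize):
        specs.append(("undersize", rng.uniform(lo * 0.3, lo * 0.7)))
    rng.shuffle(specs)

    img = np.full(shape, background, dtype=float)
    placed: list[dict] = []
    yy, xx = np.mgrid[0:h, 0:w]
    for cls, area_um2 in specs:
        radius_px = float(np.sqrt(units.um_to_px(np.sqrt(area_um2), pixel_size) ** 2 / np.pi) * np.sqrt(np.pi))
        radius_px = float(np.sqrt(area_um2 / np.pi) / pixel_size)
        ok = False
        for _ in range(10_000):
            r = rng.uniform(radius_px + 2, h - radius_px - 2)
            c = rng.uniform(radius_px + 2, w - radius_px - 2)
            if all(
                np.hypot(r - p["row"], c - p["col"]) > radius_px + p["radius_px"] + 3
                for p in placed
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not place all requested disks without overlap in 10^4 attempts"
            )
        disk = (yy - r) ** 2 + (xx - c) ** 2 <= radius_px**2
        img[disk] = foreground
        true_area_um2 = float(units.area_px_to_um2(int(disk.sum()), pixel_size))
        placed.append(
            {
                "row": r,
                "col": c,
                "radius_px": radius_px,
                "class": cls,
                "area_um2": true_area_um2,
            }
        )
    img = noise.apply(img, rng)
    in_band = sum(1 for p in placed if lo <= p["area_um2"] <= hi and p["class"] == "in_band")
    gt = GroundTruth(
        kind="puncta",
        data={
            "puncta": placed,
            "area_band": [lo, hi],
            "pixel_size": pixel_size,
            "in_band_count": in_band,
            "foreground": foreground,
            "background": background,
            "seed": seed,
        },
    )
    return img, gt


# ---------------------------------------------------------------------------
# Comet stacks
# ---------------------------------------------------------------------------

def make_comet_stack(
    speeds: Sequence[float],
    directions_deg: Sequence[float],
    n_frames: int = 20,
    dt: float = 0.5,
    pixel_size: float = 0.1,
    shape: tuple[int, int] = (128, 128),
    sigma_um: float = 0.25,
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
) -> tuple[CalibratedStack, GroundTruth]:
    """Gaussian spots translating at constant velocity (µm/s).

    Angles follow the vector convention (0° = +x/right, 90° = up =
    decreasing row). Start positions are drawn so every trajectory stays
    in frame. The ground truth stores per-comet speed and the minimum
    pairwise separation ever attained, plus an ``unambiguous_linking``
    flag when that separation exceeds twice the largest per-frame step.
    """
    speeds = np.asarray(speeds, dtype=float)
    directions = np.radians(np.asarray(directions_deg, dtype=float))
    if speeds.shape != directions.shape:
        raise ValueError("speeds and directions must have the same length")
    rng = np.random.default_rng(seed)
    h, w = shape
    steps_px = units.um_per_s_to_px_per_frame(speeds, pixel_size, dt)
    drow = -np.sin(directions) * steps_px  # up = decreasing row
    dcol = np.cos(directions) * steps_px
    total_r = drow * (n_frames - 1)
    total_c = dcol * (n_frames - 1)
    margin = 6.0
    starts = np.empty((speeds.size, 2))
    for i in range(speeds.size):
        r_lo = margin + max(0.0, -total_r[i])
        r_hi = h - margin - max(0.0, total_r[i])
        c_lo = margin + max(0.0, -total_c[i])
        c_hi = w - margin - max(0.0, total_c[i])
        if r_hi <= r_lo or c_hi <= c_lo:
            raise ValueError(f"comet {i} cannot stay in frame for {n_frames} frames")
        starts[i] = rng.uniform(r_lo, r_hi), rng.uniform(c_lo, c_hi)

    sigma_px = float(units.um_to_px(sigma_um, pixel_size))
    frames = np.empty((n_frames, h, w), dtype=float)
    traj = np.empty((n_frames, speeds.size, 2))
    for t in range(n_frames):
        traj[t, :, 0] = starts[:, 0] + drow * t
        traj[t, :, 1] = starts[:, 1] + dcol * t
        frames[t] = noise.apply(render_spots(shape, traj[t], sigma_px), rng)
    min_sep = np.inf
    if speeds.size > 1:
        for t in range(n_frames):
            d = np.linalg.norm(traj[t, :, None, :] - traj[t, None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            min_sep = min(min_sep, float(d.min()))
    stack = CalibratedStack(
        frames=frames, pixel_size=pixel_size, frame_interval=dt,
        channel_label="synthetic comets",
    )
    max_step = float(np.max(np.abs(steps_px))) if speeds.size else 0.0
    gt = GroundTruth(
        kind="comets",
        data={
            "speeds_um_s": speeds,
            "directions_deg": np.degrees(directions),
            "trajectories_px": traj,
            "min_separation_px": None if np.isinf(min_sep) else min_sep,
            "unambiguous_linking": bool(np.isinf(min_sep) or min_sep > 2 * max_step),
            "dt": dt,
            "pixel_size": pixel_size,
            "seed": seed,
        },
    )
    return stack, gt


# ---------------------------------------------------------------------------
# Embryo silhouettes
# ---------------------------------------------------------------------------

def ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's first approximation to the ellipse perimeter."""
    return float(np.pi * (3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b))))


def make_embryo_mask(
    a: float,
    b: float,
    margin_fraction: float = 0.5,
    pixel_size: float = 2.0,
    shape: tuple[int, int] = (512, 512),
) -> tuple[np.ndarray, GroundTruth]:
    """Filled elliptical silhouette with pole and margin landmarks.

    ``a`` is the semi-axis along the animal–vegetal (row) axis, ``b``
    transverse, both in µm. Landmarks: animal pole at the top of the
    ellipse, vegetal pole at the bottom, margin on the axis at
    ``margin_fraction`` of the pole-to-pole distance from the animal
    pole. Ground-truth circularity is 4πA/P² with A = πab and P the
    Ramanujan perimeter approximation.
    """
    if not (0.0 <= margin_fraction <= 1.0):
        raise ValueError("margin_fraction must be in [0, 1]")
    h, w = shape
    a_px = float(units.um_to_px(a, pixel_size))
    b_px = float(units.um_to_px(b, pixel_size))
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    if a_px >= h / 2 - 2 or b_px >= w / 2 - 2:
        raise ValueError("ellipse does not fit in the frame")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - cr) / a_px) ** 2 + ((xx - cc) / b_px) ** 2 <= 1.0
    animal = np.array([cr - a_px, cc])
    vegetal = np.array([cr + a_px, cc])
    margin = animal + margin_fraction * (vegetal - animal)
    area = np.pi * a * b
    per = ramanujan_perimeter(a, b)
    gt = GroundTruth(
        kind="embryo",
        data={
            "a_um": a,
            "b_um": b,
            "pixel_size": pixel_size,
            "animal_pole_px": animal,
            "vegetal_pole_px": vegetal,
            "margin_px": margin,
            "margin_fraction": margin_fraction,
            "circularity": 4.0 * np.pi * area / per**2,
        },
    )
    return mask, gt


# ---------------------------------------------------------------------------
# Atomic stack + sidecar output
# ---------------------------------------------------------------------------

def _save_pair(stack: CalibratedStack, gt: GroundTruth, out_dir, stem: str) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tmp_tif = out_dir / f".{stem}.tif.tmp"
    tmp_json = out_dir / f".{stem}.json.tmp"
    write_stack(stack, tmp_tif)
    gt.save(tmp_json)
    tif = out_dir / f"{stem}.tif"
    js = out_dir / f"{stem}_truth.json"
    tmp_tif.rename(tif)
    calib_tmp = tmp_tif.with_suffix(tmp_tif.suffix + ".calib.json")
    if calib_tmp.exists():
        calib_tmp.rename(tif.with_suffix(tif.suffix + ".calib.json"))
    tmp_json.rename(js)
    return tif, js


def save_artifact(stack: CalibratedStack, gt: GroundTruth, out_dir, stem: str):
    """Write a generated stack and its ground-truth sidecar atomically
    (temporary files renamed into place together)."""
    return _save_pair(stack, gt, out_dir, stem)
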