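"""Calibrated image stacks, regions of interest and result tables.

The common currency of the pipeline is the :class:`CalibratedStack`: a
``(time, rows, cols)`` intensity array carrying its spatial calibration
(µm per pixel) and frame interval (seconds per frame). All physical-unit
conversions go through the stack's accessor methods (backed by
:mod:`yolkflow.units`); downstream modules never touch ``pixel_size`` or
``frame_interval`` arithmetic themselves.

TIFF metadata is treated as untrusted: calibration is always supplied
explicitly and stored in a JSON sidecar next to written stacks (plus
standard resolution tags, which readers may ignore).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import polygon as _sk_polygon

from . import units


class CalibrationError(ValueError):
    """Nonpositive or otherwise unusable spatial/temporal calibration."""


class StackFormatError(ValueError):
    """Input image is not a single-channel grayscale multi-page TIFF."""


class RoiError(ValueError):
    """Region of interest is malformed or outside the image bounds."""


RESULT_UNITS = ("um", "um/min", "um/s", "um^2", "s", "dimensionless")


@dataclass
class CalibratedStack:
    """Time-lapse intensity stack with spatial and temporal calibration.

    Parameters
    ----------
    frames
        Array of shape ``(t, rows, cols)``, nonnegative intensities.
    pixel_size
        Micrometres per pixel, strictly positive.
    frame_interval
        Seconds per frame, strictly positive.
    channel_label
        Free-text channel description.
    valid_mask
        Optional boolean ``(rows, cols)`` mask marking pixels inside the
        analysis region (set by polygon/mask crops); ``None`` means all
        pixels are valid.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_label: str = ""
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise StackFormatError(
                f"frames must be (time, rows, cols); got shape {self.frames.shape}"
            )
        if self.pixel_size <= 0:
            raise CalibrationError(f"pixel_size must be > 0 µm/px, got {self.pixel_size}")
        if self.frame_interval <= 0:
            raise CalibrationError(
                f"frame_interval must be > 0 s/frame, got {self.frame_interval}"
            )
        if self.valid_mask is not None and self.valid_mask.shape != self.frame_shape:
            raise RoiError("valid_mask shape must match the stack's spatial shape")

    # -- basic geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    # -- unit accessors (the only sanctioned conversion sites) ----------
    def px_to_um(self, px):
        return units.px_to_um(px, self.pixel_size)

    def um_to_px(self, um):
        return units.um_to_px(um, self.pixel_size)

    def area_px_to_um2(self, px_count):
        return units.area_px_to_um2(px_count, self.pixel_size)

    def frames_to_seconds(self, frames):
        return units.frames_to_seconds(frames, self.frame_interval)

    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return self.frames_to_seconds(np.arange(self.n_frames))

    def px_per_frame_to_um_per_min(self, disp_px):
        return units.px_per_frame_to_um_per_min(
            disp_px, self.pixel_size, self.frame_interval
        )

    def um_per_min_to_px_per_frame(self, v):
        return units.um_per_min_to_px_per_frame(v, self.pixel_size, self.frame_interval)

    def px_per_frame_to_um_per_s(self, disp_px):
        return units.px_per_frame_to_um_per_s(
            disp_px, self.pixel_size, self.frame_interval
        )

    def um_per_s_to_px_per_frame(self, v):
        return units.um_per_s_to_px_per_frame(v, self.pixel_size, self.frame_interval)


@dataclass
class Roi:
    """Region of interest in pixel coordinates.

    ``kind`` is one of ``rectangle`` (``bounds = (row0, col0, height,
    width)``), ``polygon`` (``vertices`` as an ``(n, 2)`` array of
    ``(row, col)`` pairs, simple i.e. non-self-intersecting) or ``mask``
    (boolean array matching the stack's spatial shape).
    """

    kind: str
    bounds: Optional[tuple[int, int, int, int]] = None
    vertices: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind == "rectangle":
            if self.bounds is None:
                raise RoiError("rectangle roi requires bounds=(row0, col0, height, width)")
            r0, c0, h, w = self.bounds
            if h <= 0 or w <= 0:
                raise RoiError(f"rectangle must have positive height and width, got {h}x{w}")
        elif self.kind == "polygon":
            if self.vertices is None:
                raise RoiError("polygon roi requires vertices")
            self.vertices = np.asarray(self.vertices, dtype=float)
            if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
                raise RoiError("polygon vertices must be an (n>=3, 2) array of (row, col)")
            if _polygon_self_intersects(self.vertices):
                raise RoiError("polygon must be simple (non-self-intersecting)")
        elif self.kind == "mask":
            if self.mask is None:
                raise RoiError("mask roi requires a boolean mask array")
            self.mask = np.asarray(self.mask, dtype=bool)
        else:
            raise RoiError(f"unknown roi kind {self.kind!r}")

    def bounding_box(self, shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """(row0, col0, height, width) of the roi's bounding region."""
        if self.kind == "rectangle":
            return tuple(int(v) for v in self.bounds)  # type: ignore[return-value]
        if self.kind == "polygon":
            r0 = int(np.floor(self.vertices[:, 0].min()))
            c0 = int(np.floor(self.vertices[:, 1].min()))
            r1 = int(np.ceil(self.vertices[:, 0].max()))
            c1 = int(np.ceil(self.vertices[:, 1].max()))
            return r0, c0, r1 - r0 + 1, c1 - c0 + 1
        rows = np.any(self.mask, axis=1)
        cols = np.any(self.mask, axis=0)
        if not rows.any():
            raise RoiError("mask roi is empty")
        r0, r1 = np.nonzero(rows)[0][[0, -1]]
        c0, c1 = np.nonzero(cols)[0][[0, -1]]
        return int(r0), int(c0), int(r1 - r0 + 1), int(c1 - c0 + 1)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask on the full image grid."""
        if self.kind == "mask":
            if self.mask.shape != tuple(shape):
                raise RoiError("mask roi shape must match the stack's spatial shape")
            return self.mask
        out = np.zeros(shape, dtype=bool)
        if self.kind == "rectangle":
            r0, c0, h, w = self.bounds  # type: ignore[misc]
            out[r0 : r0 + h, c0 : c0 + w] = True
            return out
        rr, cc = _sk_polygon(self.vertices[:, 0], self.vertices[:, 1], shape=shape)
        out[rr, cc] = True
        return out


def _polygon_self_intersects(verts: np.ndarray) -> bool:
    """O(n²) proper-crossing check between non-adjacent edges."""
    n = len(verts)
    edges = [(verts[i], verts[(i + 1) % n]) for i in range(n)]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    for i in range(n):
        for j in range(i + 1, n):
            if abs(i - j) in (0, 1) or {i, j} == {0, n - 1}:
                continue
            p1, p2 = edges[i]
            q1, q2 = edges[j]
            d1, d2 = cross(p1, p2, q1), cross(p1, p2, q2)
            d3, d4 = cross(q1, q2, p1), cross(q1, q2, p2)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return True
    return False


@dataclass
class ResultRecord:
    """One measurement row destined for the results CSV."""

    embryo_id: str
    genotype_label: str
    stage_label: str
    measurement_name: str
    value: float
    units: str

    def __post_init__(self) -> None:
        if self.units not in RESULT_UNITS:
            raise ValueError(
                f"units {self.units!r} not in fixed vocabulary {RESULT_UNITS}"
            )


# ---------------------------------------------------------------------------
# Stack I/O
# ---------------------------------------------------------------------------

def read_stack(
    path,
    pixel_size: float,
    frame_interval: float,
    channel_label: str = "",
) -> CalibratedStack:
    """Read a single-channel multi-page TIFF into a :class:`CalibratedStack`.

    Calibration always comes from the explicit arguments; TIFF resolution
    tags are untrusted (a mismatch against a written sidecar triggers a
    warning, never an override).
    """
    if pixel_size <= 0:
        raise CalibrationError(f"pixel_size must be > 0 µm/px, got {pixel_size}")
    if frame_interval <= 0:
        raise CalibrationError(f"frame_interval must be > 0 s/frame, got {frame_interval}")
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            axes = series.axes
            if "S" in axes or "C" in axes:
                raise StackFormatError(
                    f"{path} has multi-sample/multi-channel pages (axes {axes}); "
                    "only single-channel grayscale stacks are supported"
                )
            data = series.asarray()
    except StackFormatError:
        raise
    except (OSError, ValueError, IndexError) as exc:
        raise StackFormatError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise StackFormatError(
            f"{path} is not single-channel grayscale: page shape {data.shape[1:]}"
        )
    sidecar = path.with_suffix(path.suffix + ".calib.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        for key, val in (("pixel_size", pixel_size), ("frame_interval", frame_interval)):
            if key in meta and not np.isclose(meta[key], val):
                warnings.warn(
                    f"{sidecar.name} records {key}={meta[key]} but {val} was supplied; "
                    "using the supplied value",
                    stacklevel=2,
                )
    return CalibratedStack(
        frames=data,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel_label=channel_label,
    )


def write_stack(stack: CalibratedStack, path) -> Path:
    """Write a multi-page TIFF plus a JSON calibration sidecar.

    Integer stacks round-trip bit-exactly through :func:`read_stack`.
    """
    if stack.n_frames == 0:
        raise ValueError("refusing to write an empty stack (0 frames)")
    path = Path(path)
    res = 1.0 / stack.pixel_size  # pixels per µm, stored in resolution tags
    tifffile.imwrite(
        path,
        stack.frames,
        photometric="minisblack",
        resolution=(res, res),
        metadata={"unit": "um", "frame_interval_s": stack.frame_interval},
    )
    sidecar = path.with_suffix(path.suffix + ".calib.json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size": stack.pixel_size,
                "frame_interval": stack.frame_interval,
                "channel_label": stack.channel_label,
            },
            indent=2,
        )
    )
    return path


def crop_roi(stack: CalibratedStack, roi: Roi, fill_value: float = 0.0) -> CalibratedStack:
    """Crop a stack to a roi's bounding region.

    Pixels outside a polygon/mask roi are set to ``fill_value`` and flagged
    via the returned stack's ``valid_mask``. Calibration is unchanged.
    """
    h_img, w_img = stack.frame_shape
    r0, c0, h, w = roi.bounding_box(stack.frame_shape)
    if r0 < 0 or c0 < 0 or r0 + h > h_img or c0 + w > w_img:
        raise RoiError(
            f"roi bounding box ({r0},{c0})+({h}x{w}) exceeds image bounds {h_img}x{w_img}"
        )
    sub = stack.frames[:, r0 : r0 + h, c0 : c0 + w]
    if roi.kind == "rectangle":
        return CalibratedStack(
            frames=sub.copy(),
            pixel_size=stack.pixel_size,
            frame_interval=stack.frame_interval,
            channel_label=stack.channel_label,
        )
    membership = roi.to_mask(stack.frame_shape)[r0 : r0 + h, c0 : c0 + w]
    out = sub.astype(float, copy=True)
    out[:, ~membership] = fill_value
    return CalibratedStack(
        frames=out,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
        channel_label=stack.channel_label,
        valid_mask=membership,
    )


# ---------------------------------------------------------------------------
# ROI and result-table I/O
# ---------------------------------------------------------------------------

def save_roi(roi: Roi, path) -> Path:
    path = Path(path)
    payload: dict = {"kind": roi.kind, "label": roi.label}
    if roi.kind == "rectangle":
        payload["bounds"] = [int(v) for v in roi.bounds]  # type: ignore[union-attr]
    elif roi.kind == "polygon":
        payload["vertices"] = np.asarray(roi.vertices).tolist()
    else:
        payload["mask"] = np.asarray(roi.mask, dtype=int).tolist()
    path.write_text(json.dumps(payload))
    return path


def load_roi(path) -> Roi:
    payload = json.loads(Path(path).read_text())
    kind = payload["kind"]
    if kind == "rectangle":
        return Roi(kind=kind, bounds=tuple(payload["bounds"]), label=payload.get("label", ""))
    if kind == "polygon":
        return Roi(kind=kind, vertices=np.asarray(payload["vertices"]), label=payload.get("label", ""))
    return Roi(kind=kind, mask=np.asarray(payload["mask"], dtype=bool), label=payload.get("label", ""))


TABLE_COLUMNS = ["embryo_id", "genotype", "stage", "measurement", "value", "units"]


def write_table(records: Sequence[ResultRecord], path) -> Path:
    """Write result records as CSV with a fixed header, input row order."""
    records = list(records)
    if not records:
        raise ValueError("record list is empty")
    frame = pd.DataFrame(
        [
            {
                "embryo_id": r.embryo_id,
                "genotype": r.genotype_label,
                "stage": r.stage_label,
                "measurement": r.measurement_name,
                "value": r.value,
                "units": r.units,
            }
            for r in records
        ],
        columns=TABLE_COLUMNS,
    )
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.9g")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
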