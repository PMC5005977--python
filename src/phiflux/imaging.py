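"""Dual-channel image-stack rendering and ROI trace extraction.

Stands in for the microscope + image-analysis step: cells are rendered as
uniform bright disks over a constant background, one frame per (time,
channel), and traces are recovered as mean pixel intensity per ROI with the
background estimated from a designated background ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import GeometryError
from .simulate import SeedLike, as_rng
from .traces import FluorescenceTrace


@dataclass(frozen=True)
class RoiSpec:
    """Circular ROI: center (x, y) in pixels and radius."""

    cell_id: str
    cx: float
    cy: float
    radius: float


@dataclass(frozen=True)
class RoiMap:
    rois: Tuple[RoiSpec, ...]
    field_shape: Tuple[int, int]  # (height, width)
    background_roi: Optional[RoiSpec] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rois", tuple(self.rois))
        h, w = self.field_shape
        all_rois = list(self.rois) + ([self.background_roi] if self.background_roi else [])
        for roi in all_rois:
            if (
                roi.cx - roi.radius < 0
                or roi.cy - roi.radius < 0
                or roi.cx + roi.radius > w
                or roi.cy + roi.radius > h
            ):
                raise GeometryError(f"ROI {roi.cell_id} extends outside the field")
        for i, a in enumerate(all_rois):
            for b in all_rois[i + 1 :]:
                if np.hypot(a.cx - b.cx, a.cy - b.cy) < a.radius + b.radius:
                    raise GeometryError(f"ROIs {a.cell_id} and {b.cell_id} overlap")

    def mask(self, roi: RoiSpec) -> np.ndarray:
        h, w = self.field_shape
        yy, xx = np.mgrid[0:h, 0:w]
        return (xx + 0.5 - roi.cx) ** 2 + (yy + 0.5 - roi.cy) ** 2 <= roi.radius**2


def auto_roi_map(
    cell_ids: Sequence[str],
    field_shape: Tuple[int, int] = (96, 96),
    radius: float = 6.0,
    with_background: bool = True,
) -> RoiMap:
    """Lay ROIs out on a grid with a spare corner ROI for background estimation."""
    h, w = field_shape
    pitch = int(np.ceil(2 * radius + 4))
    per_row = max(1, (w - pitch) // pitch)
    rois = []
    for i, cid in enumerate(cell_ids):
        r, c = divmod(i + (1 if with_background else 0), per_row)
        cx, cy = pitch * (c + 1), pitch * (r + 1)
        if cy + radius > h:
            raise GeometryError("too many cells for the field size")
        rois.append(RoiSpec(cid, cx, cy, radius))
    bg = RoiSpec("__background__", pitch, pitch, radius) if with_background else None
    return RoiMap(rois=tuple(rois), field_shape=field_shape, background_roi=bg)


def render_image_stack(
    traces: Sequence[FluorescenceTrace],
    roi_map: RoiMap,
    background: float = 100.0,
    noise_sd: float = 0.0,
    seed: SeedLike = 0,
) -> np.ndarray:
    """Render a stack of shape (n_frames, 2, H, W); channel 0 = I490, 1 = I440.

    Pixels inside a cell's ROI disk carry that cell's channel intensity on top
    of the constant background; optional additive Gaussian noise with SD
    ``noise_sd * sqrt(pixel value)`` emulates shot noise.
    """
    if len(traces) != len(roi_map.rois):
        raise GeometryError(
            f"{len(traces)} traces but {len(roi_map.rois)} ROIs in the map"
        )
    rng = as_rng(seed)
    h, w = roi_map.field_shape
    if traces:
        n_frames = len(traces[0].times)
    else:
        n_frames = 1
    stack = np.full((n_frames, 2, h, w), float(background))
    for trace, roi in zip(traces, roi_map.rois):
        mask = roi_map.mask(roi)
        stack[:, 0][:, mask] += trace.i490[:, None]
        stack[:, 1][:, mask] += trace.i440[:, None]
    if noise_sd > 0:
        stack = stack + noise_sd * np.sqrt(np.maximum(stack, 0)) * rng.standard_normal(
            stack.shape
        )
    return stack


def extract_roi_traces(
    stack: np.ndarray,
    roi_map: RoiMap,
    times: Optional[np.ndarray] = None,
    phase_labels: Optional[np.ndarray] = None,
) -> List[FluorescenceTrace]:
    """Mean-pixel ROI traces from a (frames, 2, H, W) stack.

    Background per channel is the time-averaged mean of the designated
    background ROI (0 if none).  An empty ROI map yields an empty list.
    """
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise GeometryError("stack must have shape (frames, 2, height, width)")
    if stack.shape[2:] != tuple(roi_map.field_shape):
        raise GeometryError("ROI map field size does not match the stack")
    n_frames = stack.shape[0]
    if times is None:
        times = np.arange(n_frames, dtype=float)
    if phase_labels is None:
        phase_labels = np.array(["HR"] * n_frames)
    bg490 = bg440 = 0.0
    if roi_map.background_roi is not None:
        mask = roi_map.mask(roi_map.background_roi)
        bg490 = float(stack[:, 0][:, mask].mean())
        bg440 = float(stack[:, 1][:, mask].mean())
    out = []
    for roi in roi_map.rois:
        mask = roi_map.mask(roi)
        out.append(
            FluorescenceTrace(
                cell_id=roi.cell_id,
                times=times,
                i490=stack[:, 0][:, mask].mean(axis=1),
                i440=stack[:, 1][:, mask].mean(axis=1),
                phase_labels=phase_labels,
                background490=bg490,
                background440=bg440,
            )
        )
    return out
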