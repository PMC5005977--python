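"""File formats: long-format trace CSV, truth CSV, flow CSV, TIFF stacks, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import RoiMap, RoiSpec
from .simulate import CohortDataset
from .traces import FluorescenceTrace, GroundTruthTrace


def traces_to_frame(traces: Sequence[FluorescenceTrace]) -> pd.DataFrame:
    """Long format: cell_id, time_s, I490, I440, phase (one row per sample)."""
    frames = [
        pd.DataFrame(
            {
                "cell_id": t.cell_id,
                "time_s": t.times,
                "I490": t.i490,
                "I440": t.i440,
                "phase": t.phase_labels,
            }
        )
        for t in traces
    ]
    return pd.concat(frames, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> List[FluorescenceTrace]:
    out = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("time_s")
        out.append(
            FluorescenceTrace(
                cell_id=str(cell_id),
                times=sub["time_s"].to_numpy(),
                i490=sub["I490"].to_numpy(),
                i440=sub["I440"].to_numpy(),
                phase_labels=sub["phase"].to_numpy(),
            )
        )
    return out


def truths_to_frame(truths: Sequence[GroundTruthTrace]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "cell_id": t.cell_id,
                "time_s": t.times,
                "ph_true": t.ph,
                "sub_label": t.sub_label or "",
            }
        )
        for t in truths
    ]
    return pd.concat(frames, ignore_index=True)


def write_cohort_csv(cohort: CohortDataset, traces_path, truth_path=None) -> None:
    traces_to_frame(cohort.traces).to_csv(traces_path, index=False)
    if truth_path is not None:
        truths_to_frame(cohort.truths).to_csv(truth_path, index=False)


def read_traces_csv(path) -> List[FluorescenceTrace]:
    return frame_to_traces(pd.read_csv(path))


# -- calibration points -------------------------------------------------------


def read_calibration_points(path) -> List:
    """Two-column CSV with header ph,ratio."""
    df = pd.read_csv(path)
    return list(zip(df["ph"], df["ratio"]))


# -- image stacks -------------------------------------------------------------


def write_stack(path, stack: np.ndarray, roi_map: RoiMap, times: np.ndarray) -> None:
    """Multi-page TIFF, page order (frame, channel), with a JSON ROI sidecar."""
    n_frames = stack.shape[0]
    pages = stack.reshape(n_frames * 2, *stack.shape[2:]).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = {
        "field_shape": list(roi_map.field_shape),
        "page_order": "(frame, channel); channel 0 = I490, 1 = I440",
        "times_s": [float(t) for t in times],
        "rois": [
            {"cell_id": r.cell_id, "cx": r.cx, "cy": r.cy, "radius": r.radius}
            for r in roi_map.rois
        ],
        "background_roi": (
            None
            if roi_map.background_roi is None
            else {
                "cell_id": roi_map.background_roi.cell_id,
                "cx": roi_map.background_roi.cx,
                "cy": roi_map.background_roi.cy,
                "radius": roi_map.background_roi.radius,
            }
        ),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path):
    """Read a stack TIFF + sidecar back to (stack, RoiMap, times)."""
    pages = tifffile.imread(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    h, w = sidecar["field_shape"]
    stack = pages.reshape(-1, 2, h, w)
    rois = tuple(
        RoiSpec(r["cell_id"], r["cx"], r["cy"], r["radius"]) for r in sidecar["rois"]
    )
    bg = sidecar["background_roi"]
    roi_map = RoiMap(
        rois=rois,
        field_shape=(h, w),
        background_roi=None if bg is None else RoiSpec(bg["cell_id"], bg["cx"], bg["cy"], bg["radius"]),
    )
    return stack, roi_map, np.asarray(sidecar["times_s"], dtype=float)


# -- YAML ---------------------------------------------------------------------


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
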