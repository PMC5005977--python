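"""Per-cell time-series containers shared by the simulator and the analysis."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

PH_PHYSIOLOGICAL_RANGE = (5.5, 8.5)


@dataclass
class GroundTruthTrace:
    """Simulator ground truth: the latent pH_i trajectory of one cell."""

    cell_id: str
    times: np.ndarray  # seconds
    ph: np.ndarray  # pH units
    preset_name: str
    true_baseline: float
    phase_labels: np.ndarray
    sub_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        self.phase_labels = np.asarray(self.phase_labels)
        if not (len(self.times) == len(self.ph) == len(self.phase_labels)):
            raise ValueError("times, ph and phase_labels must have equal length")
        lo, hi = PH_PHYSIOLOGICAL_RANGE
        if self.ph.min() < lo or self.ph.max() > hi:
            raise ValueError(f"ph outside physiological range [{lo}, {hi}]")


@dataclass
class FluorescenceTrace:
    """Dual-excitation BCECF intensities (490/440 nm ex, 535 nm em) for one cell."""

    cell_id: str
    times: np.ndarray
    i490: np.ndarray
    i440: np.ndarray
    phase_labels: np.ndarray
    background490: float = 0.0
    background440: float = 0.0
    oor_flags: Optional[np.ndarray] = None  # samples whose true pH left the curve range

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.i490 = np.asarray(self.i490, dtype=float)
        self.i440 = np.asarray(self.i440, dtype=float)
        self.phase_labels = np.asarray(self.phase_labels)
        if self.oor_flags is None:
            self.oor_flags = np.zeros(len(self.times), dtype=bool)
        else:
            self.oor_flags = np.asarray(self.oor_flags, dtype=bool)
        lengths = {len(self.times), len(self.i490), len(self.i440), len(self.phase_labels), len(self.oor_flags)}
        if len(lengths) != 1:
            raise ValueError("all trace arrays must have equal length")


@dataclass
class PhTrace:
    """Calibrated pH_i series for one cell, with per-sample validity flags."""

    cell_id: str
    times: np.ndarray
    ph: np.ndarray  # NaN where the ratio was invalid
    phase_labels: np.ndarray
    valid: np.ndarray
    oor_flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        self.phase_labels = np.asarray(self.phase_labels)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.oor_flags is None:
            self.oor_flags = np.zeros(len(self.times), dtype=bool)
        else:
            self.oor_flags = np.asarray(self.oor_flags, dtype=bool)

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())
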