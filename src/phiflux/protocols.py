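"""Superfusion protocols: ordered solution phases applied to cells in the imaging chamber.

A protocol is a contiguous sequence of phases, each defined by the bath
solution: HEPES-buffered Ringer's (HR, sodium present), HR plus ammonium
chloride (HR_NH4, the weak-base prepulse), sodium-free Ringer's (NA_FREE,
NHE1 inhibited), or the high-potassium/nigericin calibration solution
(HIGH_K_NIGERICIN, which clamps intracellular pH to the known bath pH).

Phases are half-open intervals [t_start, t_end); the final phase also owns
the protocol end point.  Analysis windows follow the same convention, so a
window such as 250-400 s sits entirely inside a single phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ProtocolError

PHASE_LABELS = ("HR", "HR_NH4", "NA_FREE", "HIGH_K_NIGERICIN")


@dataclass(frozen=True)
class PhaseSpec:
    """One bath-solution phase of a superfusion protocol.

    Parameters
    ----------
    label : str
        One of ``HR``, ``HR_NH4``, ``NA_FREE``, ``HIGH_K_NIGERICIN``.
    t_start, t_end : float
        Phase boundaries in seconds; the phase covers [t_start, t_end).
    na_present : bool
        Whether the solution contains sodium (drives NHE1 acid extrusion).
    nh4_mM : float
        Ammonium chloride concentration in mM (20 for the standard prepulse).
    known_ph : float, optional
        Bath pH during a nigericin calibration phase (required there, and
        only allowed there).
    """

    label: str
    t_start: float
    t_end: float
    na_present: bool
    nh4_mM: float = 0.0
    known_ph: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ProtocolError(f"unknown phase label {self.label!r}")
        if self.t_end <= self.t_start:
            raise ProtocolError(
                f"phase {self.label}: t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )
        if self.nh4_mM < 0:
            raise ProtocolError(f"phase {self.label}: nh4_mM must be >= 0")
        if self.nh4_mM > 0 and self.label != "HR_NH4":
            raise ProtocolError(f"phase {self.label}: nh4_mM > 0 only meaningful for HR_NH4")
        if (self.known_ph is not None) != (self.label == "HIGH_K_NIGERICIN"):
            raise ProtocolError("known_ph must be set iff label is HIGH_K_NIGERICIN")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SuperfusionProtocol:
    """Ordered, contiguous sequence of phases sampled at a fixed interval."""

    phases: tuple
    sample_interval: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if not self.phases:
            raise ProtocolError("protocol needs at least one phase")
        if self.sample_interval <= 0:
            raise ProtocolError("sample_interval must be > 0")
        prev_end = self.phases[0].t_start
        for ph in self.phases:
            if not np.isclose(ph.t_start, prev_end):
                raise ProtocolError(
                    f"phases must be contiguous: phase {ph.label} starts at "
                    f"{ph.t_start}, previous ended at {prev_end}"
                )
            prev_end = ph.t_end

    @property
    def t_start(self) -> float:
        return self.phases[0].t_start

    @property
    def t_end(self) -> float:
        return self.phases[-1].t_end

    def sample_times(self) -> np.ndarray:
        """Sample clock: multiples of sample_interval from start to end inclusive."""
        n = int(round((self.t_end - self.t_start) / self.sample_interval))
        return self.t_start + self.sample_interval * np.arange(n + 1)

    def phase_at(self, t: float) -> PhaseSpec:
        """Phase owning time t ([t_start, t_end) per phase; final phase closed)."""
        if t < self.t_start or t > self.t_end + 1e-9:
            raise ProtocolError(f"time {t} outside protocol [{self.t_start}, {self.t_end}]")
        for ph in self.phases[:-1]:
            if ph.t_start <= t < ph.t_end:
                return ph
        return self.phases[-1]

    def phase_labels(self, times: Optional[Sequence[float]] = None) -> np.ndarray:
        times = self.sample_times() if times is None else np.asarray(times, dtype=float)
        return np.array([self.phase_at(t).label for t in times])


# -- standard experiment protocols -------------------------------------------

#: Ammonium-prepulse washout: HR baseline long enough to hold the 250-400 s
#: baseline window, 20 mM NH4Cl prepulse, sodium-free washout (acid load,
#: NHE1 blocked), then sodium re-addition; recovery analysed over 1400-1800 s.
def ammonium_washout_protocol(sample_interval: float = 5.0) -> SuperfusionProtocol:
    return SuperfusionProtocol(
        phases=(
            PhaseSpec("HR", 0.0, 400.0, na_present=True),
            PhaseSpec("HR_NH4", 400.0, 700.0, na_present=True, nh4_mM=20.0),
            PhaseSpec("NA_FREE", 700.0, 1300.0, na_present=False),
            PhaseSpec("HR", 1300.0, 1800.0, na_present=True),
        ),
        sample_interval=sample_interval,
    )


#: Sodium washout: short HR baseline (first 200 s), then sodium-free
#: superfusion so the intracellular acidification rate reports endogenous
#: proton production with NHE1 efflux inhibited.
def sodium_washout_protocol(sample_interval: float = 5.0) -> SuperfusionProtocol:
    return SuperfusionProtocol(
        phases=(
            PhaseSpec("HR", 0.0, 200.0, na_present=True),
            PhaseSpec("NA_FREE", 200.0, 900.0, na_present=False),
        ),
        sample_interval=sample_interval,
    )


def with_calibration_phase(
    protocol: SuperfusionProtocol, known_ph: float, duration: float = 200.0
) -> SuperfusionProtocol:
    """Append an end-of-experiment nigericin phase clamping pH_i to known_ph."""
    cal = PhaseSpec(
        "HIGH_K_NIGERICIN",
        protocol.t_end,
        protocol.t_end + duration,
        na_present=False,
        known_ph=known_ph,
    )
    return replace(protocol, phases=protocol.phases + (cal,))
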