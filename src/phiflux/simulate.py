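"""Synthetic single-cell physiology generator.

The latent model integrates a proton budget through the intrinsic buffer
capacity::

    dpH/dt = (J_NHE - J_prod + J_NH4) / (60 * ss(pH))

with all fluxes in mM/min, ss(pH) = m*pH + b in mM per pH unit, and time in
seconds.  NHE1 extrusion is linear below its set point and requires bath
sodium: J_NHE = g * max(0, pH_set - pH) when Na+ is present, else 0.  The
ammonium prepulse is a two-jump weak-base approximation (instant alkaline
jump on application, slow acid creep while internal ammonium accumulates,
instant acid jump on removal proportional to the accumulated ammonium).
A nigericin calibration phase clamps pH_i to the known bath pH.

Each simulated cell draws its baseline from the preset's between-cell
distribution and shifts its NHE1 set point with it, so cells rest at flux
balance until perturbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import PhysiologyError, ProtocolError
from .presets import AmmoniumPulseParams, DEFAULT_PULSE, PhenotypePreset
from .protocols import SuperfusionProtocol
from .traces import FluorescenceTrace, GroundTruthTrace

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]

MARKER_CHANNELS = ("DAPI", "CD45", "TER119", "CD31")


def as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# core integrator (vectorized over cells; all cells share one protocol)
# ---------------------------------------------------------------------------


def _integrate(
    baselines: np.ndarray,
    j_prod: np.ndarray,
    gain: np.ndarray,
    setpoint: np.ndarray,
    m: np.ndarray,
    b: np.ndarray,
    protocol: SuperfusionProtocol,
    dt: Optional[float] = None,
    pulse: AmmoniumPulseParams = DEFAULT_PULSE,
) -> Tuple[np.ndarray, np.ndarray]:
    """Explicit-Euler integration of the proton budget for a batch of cells.

    Returns (sample_times, ph_matrix) with ph_matrix of shape (n_cells, n_samples).
    Phase boundaries are snapped to the sample grid; a sample at a boundary
    reports the state *after* the boundary events (jumps, clamps).
    """
    interval = protocol.sample_interval
    if dt is None:
        dt = interval / 10.0
    n_sub = max(1, int(round(interval / dt)))
    dt = interval / n_sub

    times = protocol.sample_times()
    n_samples = len(times)
    n = len(baselines)
    out = np.empty((n, n_samples))

    ph = np.array(baselines, dtype=float)
    amm = np.zeros(n)  # accumulated internal ammonium, mM
    prev_nh4 = 0.0

    # pH ceiling keeping ss >= beta_floor for each cell's buffer model (m < 0)
    with np.errstate(divide="ignore"):
        ph_cap = np.where(m < 0, (pulse.beta_floor - b) / m, np.inf)

    for phase in protocol.phases:
        k0 = int(round((phase.t_start - protocol.t_start) / interval))
        k1 = int(round((phase.t_end - protocol.t_start) / interval))
        if k1 <= k0:
            raise ProtocolError(
                f"phase {phase.label} shorter than the sample interval after snapping"
            )

        # boundary events on phase entry
        if phase.nh4_mM > prev_nh4:  # weak-base application: alkaline jump
            jump = pulse.alkaline_jump_per_mM * (phase.nh4_mM - prev_nh4)
            ph = np.minimum(ph + jump, np.maximum(ph_cap, ph))
        elif phase.nh4_mM < prev_nh4:  # removal: acid jump from trapped NH4+
            ph = ph - pulse.acid_jump_per_mM * amm
            amm[:] = 0.0
        prev_nh4 = phase.nh4_mM

        if phase.label == "HIGH_K_NIGERICIN":
            ph = np.full(n, float(phase.known_ph))
            out[:, k0 : k1 + 1] = ph[:, None]
            continue

        out[:, k0] = ph
        j_nh4 = -pulse.acid_creep_per_mM * phase.nh4_mM  # mM/min (acid load)
        for k in range(k0, k1):
            for _ in range(n_sub):
                beta = m * ph + b
                if np.any(beta <= 0):
                    raise PhysiologyError(
                        "buffer capacity reached zero on trajectory "
                        f"(pH {ph[beta <= 0][0]:.3f} in phase {phase.label})"
                    )
                j_nhe = gain * np.maximum(0.0, setpoint - ph) if phase.na_present else 0.0
                ph = ph + dt * (j_nhe - j_prod + j_nh4) / (60.0 * beta)
                if phase.nh4_mM > 0:
                    amm = amm + dt * (phase.nh4_mM - amm) / pulse.uptake_tau_s
            out[:, k + 1] = ph
    return times, out


def _draw_cell(
    preset: PhenotypePreset, rng: np.random.Generator
) -> Tuple[PhenotypePreset, Optional[str], float]:
    """Draw (component, sub_label, baseline) for one cell from a preset."""
    comps = preset.components()
    if len(comps) > 1:
        weights = np.array([w for w, _ in comps])
        idx = rng.choice(len(comps), p=weights)
        comp = comps[idx][1]
        sub_label = comp.name
    else:
        comp = comps[0][1]
        sub_label = None
    baseline = comp.ph_baseline_mean + comp.ph_baseline_sd * rng.standard_normal()
    return comp, sub_label, baseline


def simulate_ph_trajectory(
    preset: PhenotypePreset,
    protocol: SuperfusionProtocol,
    seed: SeedLike = 0,
    *,
    baseline: Optional[float] = None,
    dt: Optional[float] = None,
    pulse: AmmoniumPulseParams = DEFAULT_PULSE,
    cell_id: str = "cell0",
) -> GroundTruthTrace:
    """Simulate one cell's ground-truth pH_i trajectory under a protocol.

    If ``baseline`` is given, the between-cell draw is skipped (useful for
    noiseless, deterministic scenarios); otherwise it is drawn from the
    preset's baseline distribution (and mixture component, if any).
    """
    rng = as_rng(seed)
    comp, sub_label, drawn = _draw_cell(preset, rng)
    if baseline is not None:
        drawn = float(baseline)
    setpoint = comp.nhe_setpoint + (drawn - comp.ph_baseline_mean)
    times, ph = _integrate(
        np.array([drawn]),
        np.array([comp.proton_production]),
        np.array([comp.nhe_gain]),
        np.array([setpoint]),
        np.array([comp.buffer_slope]),
        np.array([comp.buffer_intercept]),
        protocol,
        dt=dt,
        pulse=pulse,
    )
    return GroundTruthTrace(
        cell_id=cell_id,
        times=times,
        ph=ph[0],
        preset_name=preset.name,
        true_baseline=drawn,
        phase_labels=protocol.phase_labels(times),
        sub_label=sub_label,
    )


def render_fluorescence(
    truth: GroundTruthTrace,
    curve,
    noise_sd: float = 0.005,
    bleach_rate: float = 2e-5,
    seed: SeedLike = 0,
    base_i440: float = 1000.0,
) -> FluorescenceTrace:
    """Render dual-channel BCECF intensities from a ground-truth pH trace.

    The 440 nm channel is a pH-independent reference; the 490 nm channel
    carries the pH signal through the calibration curve's ratio prediction.
    Both channels share one exponential photobleaching factor (so the ratio
    is bleach-invariant in expectation) and receive independent
    multiplicative Gaussian noise.  Samples whose true pH lies outside the
    curve's validity range are flagged, not clipped.
    """
    rng = as_rng(seed)
    ratio = curve.predict_ratio(truth.ph)
    lo, hi = curve.valid_range
    oor = (truth.ph < lo) | (truth.ph > hi)
    decay = np.exp(-bleach_rate * (truth.times - truth.times[0]))
    eps490 = rng.standard_normal(len(truth.times))
    eps440 = rng.standard_normal(len(truth.times))
    i440 = base_i440 * decay * (1.0 + noise_sd * eps440)
    i490 = ratio * base_i440 * decay * (1.0 + noise_sd * eps490)
    return FluorescenceTrace(
        cell_id=truth.cell_id,
        times=truth.times,
        i490=i490,
        i440=i440,
        phase_labels=truth.phase_labels,
        oor_flags=oor,
    )


@dataclass
class CohortDataset:
    """Matched fluorescence traces and their ground truths for one simulated cohort."""

    traces: List[FluorescenceTrace]
    truths: List[GroundTruthTrace]
    protocol: SuperfusionProtocol

    def __len__(self) -> int:
        return len(self.traces)

    def group_of(self, cell_id: str) -> str:
        for t in self.truths:
            if t.cell_id == cell_id:
                return t.sub_label or t.preset_name
        raise KeyError(cell_id)


def simulate_cohort(
    preset_counts: Sequence[Tuple[PhenotypePreset, int]],
    protocol: SuperfusionProtocol,
    seed: SeedLike = 0,
    *,
    curve=None,
    noise_sd: float = 0.005,
    bleach_rate: float = 2e-5,
    dt: Optional[float] = None,
    pulse: AmmoniumPulseParams = DEFAULT_PULSE,
) -> CohortDataset:
    """Simulate a cohort of cells (several presets, n cells each) and render them.

    Per-cell randomness is drawn from children of ``SeedSequence(seed)``
    (one child per cell, split into a trajectory stream and a render
    stream), so a cohort is bit-reproducible and each cell equals a
    standalone ``simulate_ph_trajectory`` + ``render_fluorescence`` run
    with the corresponding child seeds.
    """
    from .calibration import default_curve  # local import to avoid a cycle

    if curve is None:
        curve = default_curve()
    for _, n in preset_counts:
        if n < 1:
            raise ValueError("n_cells must be >= 1 for every preset")

    total = sum(n for _, n in preset_counts)
    if isinstance(seed, np.random.SeedSequence):
        # fresh copy so repeated calls with the same SeedSequence are identical
        ss = np.random.SeedSequence(entropy=seed.entropy, spawn_key=seed.spawn_key)
    else:
        ss = np.random.SeedSequence(seed)
    children = ss.spawn(total)

    # per-cell draws (same order as simulate_ph_trajectory would make them)
    cells = []  # (cell_id, comp, sub_label, baseline, preset_name, render_ss)
    idx = 0
    for preset, n in preset_counts:
        for j in range(n):
            traj_ss, render_ss = children[idx].spawn(2)
            rng = np.random.default_rng(traj_ss)
            comp, sub_label, baseline = _draw_cell(preset, rng)
            cell_id = f"{preset.name}_{j:03d}"
            cells.append((cell_id, comp, sub_label, baseline, preset.name, render_ss))
            idx += 1

    times, ph = _integrate(
        np.array([c[3] for c in cells]),
        np.array([c[1].proton_production for c in cells]),
        np.array([c[1].nhe_gain for c in cells]),
        np.array([c[1].nhe_setpoint + (c[3] - c[1].ph_baseline_mean) for c in cells]),
        np.array([c[1].buffer_slope for c in cells]),
        np.array([c[1].buffer_intercept for c in cells]),
        protocol,
        dt=dt,
        pulse=pulse,
    )
    labels = protocol.phase_labels(times)

    truths, traces = [], []
    for i, (cell_id, comp, sub_label, baseline, preset_name, render_ss) in enumerate(cells):
        truth = GroundTruthTrace(
            cell_id=cell_id,
            times=times,
            ph=ph[i],
            preset_name=preset_name,
            true_baseline=baseline,
            phase_labels=labels,
            sub_label=sub_label,
        )
        truths.append(truth)
        traces.append(
            render_fluorescence(
                truth, curve, noise_sd=noise_sd, bleach_rate=bleach_rate, seed=render_ss
            )
        )
    return CohortDataset(traces=traces, truths=truths, protocol=protocol)


# ---------------------------------------------------------------------------
# flow-cytometry event simulation
# ---------------------------------------------------------------------------

#: log10 fluorescence of marker-negative / marker-positive events
MARKER_NEG_LOG, MARKER_POS_LOG, MARKER_LOG_SD = 1.5, 3.5, 0.15


def simulate_flow_events(
    preset_counts: Sequence[Tuple[PhenotypePreset, int]],
    contamination: Optional[Mapping[str, float]] = None,
    seed: SeedLike = 0,
) -> pd.DataFrame:
    """Simulate a 2-NBDG flow-cytometry event table with lineage/viability markers.

    ``contamination`` maps marker channels (DAPI, CD45, TER119, CD31) to the
    fraction of events positive on exactly that marker (dead cells /
    hematopoietic / erythroid / endothelial events); the remaining events are
    marker-negative target cells.  2-NBDG intensity is log-normal per preset
    component; columns are NBDG, the four marker channels, and truth_label.
    """
    contamination = dict(contamination or {})
    for ch in contamination:
        if ch not in MARKER_CHANNELS:
            raise ValueError(f"unknown contamination channel {ch!r}")
    fracs = np.array([contamination.get(ch, 0.0) for ch in MARKER_CHANNELS])
    if (fracs < 0).any() or fracs.sum() >= 1.0:
        raise ValueError("contamination fractions must be >= 0 and sum to < 1")

    rng = as_rng(seed)
    frames = []
    classes = ["clean"] + list(MARKER_CHANNELS)
    probs = np.concatenate([[1.0 - fracs.sum()], fracs])
    for preset, n in preset_counts:
        comps = preset.components()
        weights = np.array([w for w, _ in comps])
        comp_idx = rng.choice(len(comps), size=n, p=weights)
        log_mean = np.array([c.nbdg_log_mean for _, c in comps])[comp_idx]
        log_sd = np.array([c.nbdg_log_sd for _, c in comps])[comp_idx]
        nbdg = 10.0 ** rng.normal(log_mean, log_sd)

        cls_idx = rng.choice(len(classes), size=n, p=probs)
        cols = {"NBDG": nbdg}
        for ci, ch in enumerate(MARKER_CHANNELS, start=1):
            log_level = np.where(cls_idx == ci, MARKER_POS_LOG, MARKER_NEG_LOG)
            cols[ch] = 10.0 ** rng.normal(log_level, MARKER_LOG_SD)
        labels = np.array(
            [c.name for _, c in comps], dtype=object
        )[comp_idx]
        labels = np.where(cls_idx == 0, labels, np.array(classes, dtype=object)[cls_idx] + "+")
        cols["truth_label"] = labels
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)
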