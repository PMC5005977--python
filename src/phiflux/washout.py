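"""Washout analysis: ratios, calibrated pH traces, windowed statistics, proton fluxes.

The measurement chain per cell is

    F490, F440  ->  background-corrected ratio  ->  calibrated pH_i(t)
    -> baseline mean over an HR window
    -> OLS slope dpH_i/dt over a phase window
    -> flux = ss(pH_ref) * |dpH_i/dt| * 60   (mM/min)

with ss the cell class's intrinsic buffer capacity evaluated at the window's
mean pH.  During sodium-free superfusion the acidification slope reports
endogenous proton production; during sodium re-addition after an acid load
the recovery slope reports net NHE1 extrusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibration import CalibrationCurve
from .errors import QCError, WindowError
from .presets import BufferCapacityModel
from .traces import FluorescenceTrace, PhTrace

#: Printed analysis windows (seconds, half-open [t0, t1)).
AMMONIUM_BASELINE_WINDOW = (250.0, 400.0)
RECOVERY_WINDOW = (1400.0, 1800.0)
SODIUM_BASELINE_WINDOW = (0.0, 200.0)
SODIUM_ACID_WINDOW = (200.0, 900.0)
#: "Initial flux" window: first 60 s of the recovery phase (sodium re-addition).
INITIAL_RECOVERY_WINDOW = (1300.0, 1360.0)

MAX_INVALID_FRACTION = 0.01


def compute_ratio(trace: FluorescenceTrace, max_invalid: float = MAX_INVALID_FRACTION):
    """Background-corrected F490/F440 ratio per sample.

    Samples with a non-positive corrected denominator are flagged invalid
    (NaN) without affecting their neighbours; more than ``max_invalid`` of
    invalid samples fails trace QC.
    """
    num = trace.i490 - trace.background490
    den = trace.i440 - trace.background440
    valid = den > 0
    ratio = np.where(valid, num, np.nan) / np.where(valid, den, 1.0)
    ratio = np.where(valid, ratio, np.nan)
    frac_invalid = 1.0 - valid.mean()
    if frac_invalid > max_invalid:
        raise QCError(
            f"trace {trace.cell_id}: {frac_invalid:.1%} invalid ratio samples "
            f"(limit {max_invalid:.0%})"
        )
    return ratio, valid


def trace_to_ph(trace: FluorescenceTrace, curve: CalibrationCurve) -> PhTrace:
    """Calibrate one fluorescence trace to a pH_i time series."""
    ratio, valid = compute_ratio(trace)
    ph, oor, inv_valid = curve.ratio_to_ph(ratio)
    return PhTrace(
        cell_id=trace.cell_id,
        times=trace.times,
        ph=ph,
        phase_labels=trace.phase_labels,
        valid=valid & inv_valid,
        oor_flags=oor,
    )


def _window_mask(ph_trace: PhTrace, window: Tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if t1 <= t0:
        raise WindowError(f"empty window [{t0}, {t1})")
    mask = (ph_trace.times >= t0) & (ph_trace.times < t1)
    labels = np.unique(ph_trace.phase_labels[mask])
    if len(labels) > 1:
        raise WindowError(
            f"window [{t0}, {t1}) crosses a phase boundary (phases {list(labels)})"
        )
    return mask & ph_trace.valid


@dataclass(frozen=True)
class BaselineResult:
    mean: float
    sem: float
    n: int
    window: Tuple[float, float]


def baseline_ph(ph_trace: PhTrace, window: Tuple[float, float]) -> BaselineResult:
    """Arithmetic mean +/- SEM of pH_i over a window inside one HR phase."""
    mask = _window_mask(ph_trace, window)
    vals = ph_trace.ph[mask]
    if len(vals) < 3:
        raise WindowError(f"baseline window {window} holds {len(vals)} samples (< 3)")
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return BaselineResult(mean=float(vals.mean()), sem=sem, n=len(vals), window=window)


@dataclass(frozen=True)
class SlopeFit:
    slope: float  # pH/s
    intercept: float
    ci: Tuple[float, float]  # 95% CI on the slope
    r_squared: float
    n: int
    window: Tuple[float, float]
    mean_ph: float  # window-mean pH, used as pH_ref for flux


def fit_slope(ph_trace: PhTrace, window: Tuple[float, float]) -> SlopeFit:
    """Ordinary least-squares slope of pH_i vs time within a window (pH/s)."""
    mask = _window_mask(ph_trace, window)
    t, y = ph_trace.times[mask], ph_trace.ph[mask]
    if len(t) < 5:
        raise WindowError(f"slope window {window} holds {len(t)} samples (< 5)")
    res = sps.linregress(t, y)
    tcrit = sps.t.ppf(0.975, len(t) - 2)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci=(float(res.slope - tcrit * res.stderr), float(res.slope + tcrit * res.stderr)),
        r_squared=float(res.rvalue**2),
        n=len(t),
        window=window,
        mean_ph=float(y.mean()),
    )


def buffer_capacity(model: BufferCapacityModel, ph: float) -> float:
    """Intrinsic buffer capacity ss(pH) = m*pH + b in mM per pH unit."""
    lo, hi = 6.2, 8.2
    if not (lo <= ph <= hi):
        warnings.warn(
            f"pH {ph:.3f} outside the calibrated range [{lo}, {hi}]; "
            "extrapolating the linear buffer model",
            stacklevel=2,
        )
    return float(model.beta(ph))


def proton_flux(beta: float, slope: float, direction: str = "efflux") -> float:
    """Proton flux in mM/min: ss * |dpH_i/dt| * 60, positive for ``direction``.

    ``efflux`` for acid extrusion during recovery (pH rising), ``production``
    for acid loading during sodium-free superfusion (pH falling).
    """
    if beta <= 0:
        raise ValueError("buffer capacity must be > 0")
    if direction not in ("efflux", "production"):
        raise ValueError("direction must be 'efflux' or 'production'")
    return beta * abs(slope) * 60.0


@dataclass
class WashoutResult:
    """Per-cell washout analysis summary."""

    cell_id: str
    baseline: BaselineResult
    slopes: List[SlopeFit]
    beta_at_ph: float  # ss at the flux window's mean pH
    flux: float  # mM/min, positive in the stated direction
    flux_direction: str
    group: Optional[str] = None
    qc_flags: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "cell_id": self.cell_id,
            "group": self.group,
            "baseline_ph": self.baseline.mean,
            "baseline_sem": self.baseline.sem,
            "baseline_window": f"{self.baseline.window[0]}-{self.baseline.window[1]}",
            "beta_at_ph": self.beta_at_ph,
            "flux_mM_min": self.flux,
            "flux_direction": self.flux_direction,
            "qc_flags": ";".join(self.qc_flags),
        }
        for i, s in enumerate(self.slopes):
            d[f"slope{i}_window"] = f"{s.window[0]}-{s.window[1]}"
            d[f"slope{i}_ph_per_s"] = s.slope
            d[f"slope{i}_r2"] = s.r_squared
        return d


def analyze_washout(
    ph_trace: PhTrace,
    buffer_model: BufferCapacityModel,
    baseline_window: Tuple[float, float],
    slope_windows: Sequence[Tuple[float, float]],
    flux_window_index: int = 0,
    flux_direction: str = "efflux",
    group: Optional[str] = None,
) -> WashoutResult:
    """Full per-cell analysis: baseline, slopes, buffer capacity, flux.

    ``flux_window_index`` selects which fitted slope the flux is computed
    from; ss is evaluated at that window's mean pH.
    """
    base = baseline_ph(ph_trace, baseline_window)
    slopes = [fit_slope(ph_trace, w) for w in slope_windows]
    sel = slopes[flux_window_index]
    beta = buffer_capacity(buffer_model, sel.mean_ph)
    flux = proton_flux(beta, sel.slope, direction=flux_direction)
    qc = []
    if ph_trace.n_invalid:
        qc.append(f"invalid_samples={ph_trace.n_invalid}")
    if int(np.asarray(ph_trace.oor_flags).sum()):
        qc.append(f"out_of_range_samples={int(np.asarray(ph_trace.oor_flags).sum())}")
    return WashoutResult(
        cell_id=ph_trace.cell_id,
        baseline=base,
        slopes=slopes,
        beta_at_ph=beta,
        flux=flux,
        flux_direction=flux_direction,
        group=group,
        qc_flags=tuple(qc),
    )


def analyze_cohort(
    ph_traces: Sequence[PhTrace],
    buffer_model: BufferCapacityModel,
    baseline_window: Tuple[float, float],
    slope_windows: Sequence[Tuple[float, float]],
    groups: Optional[Sequence[Optional[str]]] = None,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`analyze_washout` per cell and tabulate the results."""
    if groups is None:
        groups = [None] * len(ph_traces)
    rows = [
        analyze_washout(
            tr, buffer_model, baseline_window, slope_windows, group=g, **kwargs
        ).to_dict()
        for tr, g in zip(ph_traces, groups)
    ]
    return pd.DataFrame(rows)
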