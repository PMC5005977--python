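"""End-to-end synthetic experiments that recompute the study's headline numbers.

Every function here runs the full measurement chain — simulate a cohort,
render fluorescence, fit the nigericin standard curve, calibrate the traces,
and apply the analysis — so the returned numbers are computed, never stored.
Replicate seeds are spawned from a single master seed.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .calibration import default_curve, fit_calibration
from .presets import AMMONIUM_PRESETS, SODIUM_PRESETS, PhenotypePreset
from .protocols import (
    SuperfusionProtocol,
    ammonium_washout_protocol,
    sodium_washout_protocol,
)
from .simulate import CohortDataset, simulate_cohort
from .stats import pointwise_welch, split_bimodal
from .washout import (
    AMMONIUM_BASELINE_WINDOW,
    RECOVERY_WINDOW,
    SODIUM_ACID_WINDOW,
    SODIUM_BASELINE_WINDOW,
    baseline_ph,
    trace_to_ph,
)

#: Default nigericin standard-curve pH points (the 6.2-8.2 five-point curve).
CALIBRATION_PHS = (6.2, 6.7, 7.2, 7.7, 8.2)


def fitted_default_curve():
    """Fit the standard curve from five nigericin calibration points.

    The points lie on the simulator's instrument response, so the fitted
    curve exercises the calibration path without introducing bias.
    """
    truth = default_curve()
    points = [(ph, float(truth.predict_ratio(ph))) for ph in CALIBRATION_PHS]
    return fit_calibration(points)


def _rep_seeds(seed: int, n_reps: int) -> List[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n_reps)


def cohort_ph_matrix(cohort: CohortDataset, curve) -> np.ndarray:
    """Calibrated pH matrix (cells x timepoints) for a cohort."""
    return np.vstack([trace_to_ph(tr, curve).ph for tr in cohort.traces])


def cohort_baselines(cohort: CohortDataset, curve, window) -> np.ndarray:
    return np.array(
        [baseline_ph(trace_to_ph(tr, curve), window).mean for tr in cohort.traces]
    )


# ---------------------------------------------------------------------------
# headline experiments
# ---------------------------------------------------------------------------


def pyvmt_baseline_experiment(seed: int, n_reps: int = 20, n_cells: int = 10) -> Dict:
    """Group-mean baseline pH_i of synthetic PyVmT ammonium-washout cohorts.

    Ten cells per replicate, baseline over the 250-400 s HR window, median
    over replicates.
    """
    protocol = ammonium_washout_protocol()
    curve = fitted_default_curve()
    means = []
    for ss in _rep_seeds(seed, n_reps):
        cohort = simulate_cohort([(AMMONIUM_PRESETS["PyVmT"], n_cells)], protocol, seed=ss)
        means.append(float(cohort_baselines(cohort, curve, AMMONIUM_BASELINE_WINDOW).mean()))
    return {"value": float(np.median(means)), "n": n_cells, "per_rep": means}


def mino_split_experiment(seed: int, n_reps: int = 20, n_cells: int = 68) -> Dict:
    """Bimodal split of synthetic MINO sodium-washout cohorts.

    68 cells drawn from the two-component MINO mixture, baseline over the
    first 200 s, exact two-means split on the per-cell baselines; reports the
    median high-group and low-group means over replicates.
    """
    protocol = sodium_washout_protocol()
    curve = fitted_default_curve()
    highs, lows = [], []
    for ss in _rep_seeds(seed, n_reps):
        cohort = simulate_cohort([(SODIUM_PRESETS["MINO"], n_cells)], protocol, seed=ss)
        baselines = cohort_baselines(cohort, curve, SODIUM_BASELINE_WINDOW)
        split = split_bimodal(baselines)
        highs.append(float(baselines[split.high_mask].mean()))
        lows.append(float(baselines[~split.high_mask].mean()))
    return {
        "high": float(np.median(highs)),
        "low": float(np.median(lows)),
        "n": n_cells,
        "per_rep_high": highs,
        "per_rep_low": lows,
    }


def welch_fraction_experiment(
    seed: int,
    n_reps: int = 20,
    n_nmec: int = 39,
    n_met1: int = 108,
    t_max: float = 430.0,
) -> Dict:
    """Percent of sodium-washout timepoints before 430 s with Welch p < 0.05.

    nMEC vs Met1 cohorts at the observed group sizes (3 and 6 coverslips at
    ~13 and ~18 cells each); median over replicates.
    """
    protocol = sodium_washout_protocol()
    curve = fitted_default_curve()
    times = protocol.sample_times()
    fracs = []
    for ss in _rep_seeds(seed, n_reps):
        a, b = ss.spawn(2)
        co_n = simulate_cohort([(SODIUM_PRESETS["nMEC"], n_nmec)], protocol, seed=a)
        co_m = simulate_cohort([(SODIUM_PRESETS["Met1"], n_met1)], protocol, seed=b)
        res = pointwise_welch(
            cohort_ph_matrix(co_n, curve),
            cohort_ph_matrix(co_m, curve),
            times,
            interval=(0.0, t_max),
        )
        fracs.append(100.0 * res.frac_significant)
    return {"value": float(np.median(fracs)), "n": n_nmec + n_met1, "per_rep": fracs}


def pooled_slope_experiment(
    preset: PhenotypePreset,
    protocol: SuperfusionProtocol,
    window: Tuple[float, float],
    seed: int,
    n_reps: int = 20,
    n_cells: int = 5,
) -> Dict:
    """Seed-averaged pooled regression slope (pH/s) over a window.

    Pools all cells' calibrated (time, pH) samples in the window into a
    single OLS fit per replicate, then averages replicates.
    """
    from scipy.stats import linregress

    curve = fitted_default_curve()
    slopes = []
    for ss in _rep_seeds(seed, n_reps):
        cohort = simulate_cohort([(preset, n_cells)], protocol, seed=ss)
        ts, ys = [], []
        for tr in cohort.traces:
            pt = trace_to_ph(tr, curve)
            mask = (pt.times >= window[0]) & (pt.times < window[1]) & pt.valid
            ts.append(pt.times[mask])
            ys.append(pt.ph[mask])
        res = linregress(np.concatenate(ts), np.concatenate(ys))
        slopes.append(float(res.slope))
    return {"value": float(np.mean(slopes)), "n": n_cells, "per_rep": slopes}


def baseline_recovery_experiment(
    preset: PhenotypePreset,
    protocol: SuperfusionProtocol,
    window: Tuple[float, float],
    seed: int,
    n_reps: int = 20,
    n_cells: int = 10,
) -> Dict:
    """Median-over-replicates group-mean baseline pH_i for one preset."""
    curve = fitted_default_curve()
    means = []
    for ss in _rep_seeds(seed, n_reps):
        cohort = simulate_cohort([(preset, n_cells)], protocol, seed=ss)
        means.append(float(cohort_baselines(cohort, curve, window).mean()))
    return {"value": float(np.median(means)), "n": n_cells, "per_rep": means}


def run_targets(seed: int, n_reps: int = 20) -> Dict[str, Dict]:
    """Recompute the headline quantities; returns {name: {value, n}}."""
    t4 = pyvmt_baseline_experiment(seed, n_reps=n_reps)
    split = mino_split_experiment(seed + 1, n_reps=n_reps)
    t8 = welch_fraction_experiment(seed + 2, n_reps=n_reps)
    return {
        "t4": {"value": round(t4["value"], 4), "n": t4["n"]},
        "t6": {"value": round(split["high"], 4), "n": split["n"]},
        "t7": {"value": round(split["low"], 4), "n": split["n"]},
        "t8": {"value": round(t8["value"], 2), "n": t8["n"]},
    }
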