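"""Group-level statistics for washout cohorts.

Covers the four comparisons used on the washout data: an exact 1-D
two-group split of baseline pH_i (the MINO high/low separation),
per-timepoint Welch t-tests between two cohorts, ANCOVA on regression
slopes (group x time interaction in a general linear model), and one-way
ANOVA with the Student-Newman-Keuls post-hoc stepping on studentized-range
critical values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import SplitError


@dataclass(frozen=True)
class GroupSummary:
    """Baseline summary for one group of cells."""

    group: str
    n_cells: int
    mean_baseline: float
    sem: float
    window: Tuple[float, float]
    n_coverslips: Optional[int] = None


def summarize_groups(
    baselines_by_group: Mapping[str, Sequence[float]],
    window: Tuple[float, float],
    coverslips: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Tabulate per-group mean baseline pH_i +/- SEM (SEM over cells)."""
    rows = []
    for g, vals in baselines_by_group.items():
        v = np.asarray(vals, dtype=float)
        rows.append(
            {
                "group": g,
                "n_cells": len(v),
                "n_coverslips": (coverslips or {}).get(g),
                "mean_baseline": float(v.mean()),
                "sem": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
                "window": f"{window[0]}-{window[1]}",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact 1-D two-means split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitResult:
    threshold: float
    labels: np.ndarray  # "high"/"low" per input cell, original order
    within_group_variance: float  # pooled within-group SS / n
    method: str = "exact_2means"

    @property
    def high_mask(self) -> np.ndarray:
        return self.labels == "high"


def split_bimodal(baselines: Sequence[float]) -> SplitResult:
    """Exact 1-D two-means split of per-cell baseline pH values.

    Exhaustively scans the n-1 thresholds between sorted values and keeps the
    cut minimizing pooled within-group sum of squares (equivalent to 1-D
    k-means with k=2).  Ties are broken toward the lower threshold.  The
    returned threshold is the midpoint of the boundary pair, so every high
    baseline is >= threshold > every low baseline.
    """
    x = np.asarray(baselines, dtype=float)
    if len(x) < 4:
        raise SplitError(f"bimodal split needs >= 4 cells, got {len(x)}")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    # prefix sums give O(n) evaluation of all cuts
    csum = np.cumsum(xs)
    csum2 = np.cumsum(xs**2)
    best_k, best_ss = None, np.inf
    for k in range(1, n):  # low group = xs[:k]
        ss_low = csum2[k - 1] - csum[k - 1] ** 2 / k
        ss_high = (csum2[-1] - csum2[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
        ss = ss_low + ss_high
        if ss < best_ss - 1e-15:  # strict improvement keeps the lower threshold
            best_ss, best_k = ss, k
    threshold = 0.5 * (xs[best_k - 1] + xs[best_k])
    labels = np.where(x >= threshold, "high", "low")
    return SplitResult(
        threshold=float(threshold),
        labels=labels,
        within_group_variance=float(best_ss / n),
    )


# ---------------------------------------------------------------------------
# per-timepoint Welch t-tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WelchResult:
    times: np.ndarray
    p_values: np.ndarray  # NaN where undefined (zero variance in both groups)
    n_excluded: int
    frac_significant: float
    interval: Tuple[float, float]
    alpha: float


def pointwise_welch(
    group_a: np.ndarray,
    group_b: np.ndarray,
    times: np.ndarray,
    alpha: float = 0.05,
    interval: Optional[Tuple[float, float]] = None,
    correction: str = "none",
) -> WelchResult:
    """Two-sided Welch t-test per timepoint between two cohorts.

    ``group_a`` and ``group_b`` are (cells x timepoints) matrices on a common
    time grid.  Timepoints where both groups have zero variance are excluded
    and counted.  ``frac_significant`` is the fraction of testable timepoints
    within ``interval`` (default: whole grid) with p < alpha.  Per-timepoint
    p-values are uncorrected by default; ``correction="bh"`` applies
    Benjamini-Hochberg across timepoints.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    times = np.asarray(times, dtype=float)
    if a.shape[1] != len(times) or b.shape[1] != len(times):
        raise ValueError("groups must share the common time grid")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs >= 2 cells")
    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.where(degenerate, np.nan, res.pvalue)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        finite = np.isfinite(p)
        if finite.any():
            p = p.copy()
            p[finite] = multipletests(p[finite], method="fdr_bh")[1]
    elif correction != "none":
        raise ValueError("correction must be 'none' or 'bh'")
    if interval is None:
        interval = (float(times.min()), float(times.max()) + 1.0)
    t0, t1 = interval
    in_win = (times >= t0) & (times < t1)
    testable = in_win & np.isfinite(p)
    frac = float((p[testable] < alpha).mean()) if testable.any() else np.nan
    return WelchResult(
        times=times,
        p_values=p,
        n_excluded=int((in_win & ~np.isfinite(p)).sum()),
        frac_significant=frac,
        interval=(t0, t1),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# ANCOVA on slopes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AncovaResult:
    f_statistic: float
    p_value: float
    slopes: Dict[str, float]  # per-group OLS slopes (pH/s)
    df: Tuple[float, float]


def ancova_slopes(
    data: pd.DataFrame, window: Optional[Tuple[float, float]] = None
) -> AncovaResult:
    """Compare regression slopes across groups via the group x time interaction.

    ``data`` has columns ``time``, ``ph``, ``group``.  Fits the general
    linear model ph ~ time * group and F-tests the interaction term against
    the common-slope model.  Per-group slopes come from per-group OLS fits
    (identical to the interaction-model estimates).
    """
    df = data.copy()
    if window is not None:
        t0, t1 = window
        df = df[(df["time"] >= t0) & (df["time"] < t1)]
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("ANCOVA needs >= 2 groups")
    for g in groups:
        sub = df[df["group"] == g]
        if len(sub) < 5:
            raise ValueError(f"group {g!r} has {len(sub)} points (< 5) in the window")
        if sub["time"].nunique() < 2:
            raise ValueError(f"group {g!r} has no time variation (singular design)")
    full = smf.ols("ph ~ time * C(group)", data=df).fit()
    reduced = smf.ols("ph ~ time + C(group)", data=df).fit()
    table = anova_lm(reduced, full)
    f = float(table["F"].iloc[1])
    p = float(table["Pr(>F)"].iloc[1])
    slopes = {
        str(g): float(sps.linregress(sub["time"], sub["ph"]).slope)
        for g, sub in df.groupby("group")
    }
    return AncovaResult(
        f_statistic=f,
        p_value=p,
        slopes=slopes,
        df=(float(table["df_diff"].iloc[1]), float(table["df_resid"].iloc[1])),
    )


# ---------------------------------------------------------------------------
# one-way ANOVA + Student-Newman-Keuls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnkResult:
    anova_f: float
    anova_p: float
    table: pd.DataFrame  # pair, mean_diff, span, q, p, significant


def anova_snk(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> SnkResult:
    """One-way ANOVA followed by the Student-Newman-Keuls multiple comparison.

    SNK steps through pairs by the rank span r of their means, using the
    studentized-range distribution with the ANOVA error df; a pair is only
    tested if no enclosing non-significant span has already covered it
    (standard step-down protection).  Harmonic mean group size handles
    unequal n.
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError("SNK stepping needs >= 3 groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has n < 2")
    anova = sps.f_oneway(*arrays.values())
    n_total = sum(len(a) for a in arrays.values())
    k = len(names)
    df_err = n_total - k
    grand = {g: a.mean() for g, a in arrays.items()}
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_err

    ranked = sorted(names, key=lambda g: grand[g])
    rank = {g: i for i, g in enumerate(ranked)}
    # process spans from widest to narrowest; non-significant spans shield inner pairs
    shielded = set()
    rows = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    pairs.sort(key=lambda ab: -(abs(rank[ab[0]] - rank[ab[1]]) + 1))
    for a, b in pairs:
        lo, hi = sorted((rank[a], rank[b]))
        r = hi - lo + 1
        n_h = sps.hmean([len(arrays[a]), len(arrays[b])])
        q = abs(grand[a] - grand[b]) / np.sqrt(mse / n_h)
        p = float(sps.studentized_range.sf(q, r, df_err))
        sig = p < alpha and (a, b) not in shielded and (b, a) not in shielded
        if anova.pvalue >= alpha:
            sig = False
        if not sig:
            # shield every pair nested within this span
            for g1 in ranked[lo : hi + 1]:
                for g2 in ranked[lo : hi + 1]:
                    if g1 != g2:
                        shielded.add((g1, g2))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": grand[a] - grand[b],
                "span": r,
                "q": float(q),
                "p": p,
                "significant": bool(sig),
            }
        )
    return SnkResult(
        anova_f=float(anova.statistic),
        anova_p=float(anova.pvalue),
        table=pd.DataFrame(rows),
    )
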