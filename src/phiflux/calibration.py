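"""BCECF ratio-to-pH calibration.

A five-point high-K+/nigericin standard curve maps the background-corrected
F490/F440 excitation ratio to pH over 6.2-8.2.  The default model is linear
(adequate near the BCECF pK over this range); a four-parameter logistic is
available for stress testing.  Instrument drift between the standard curve
and an experiment is corrected with a single end-of-experiment calibration
point applied as a multiplicative scale on the predicted ratio.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence, Tuple

import numpy as np
from scipy import optimize

from .errors import CalibrationError, RescaleError

log = logging.getLogger(__name__)

DEFAULT_VALID_RANGE = (6.2, 8.2)


def _sigmoid(ph, lo, hi, mid, width):
    return lo + (hi - lo) / (1.0 + np.exp(-(np.asarray(ph, dtype=float) - mid) / width))


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted ratio-vs-pH mapping with validity range and one-point scale.

    ``params`` are (slope, intercept) for the linear model or
    (lo, hi, mid, width) for the sigmoid.  The predicted ratio is
    ``scale * f(pH)``; ``scale`` defaults to 1 and is set by
    :func:`one_point_rescale`.
    """

    model: str
    params: Tuple[float, ...]
    valid_range: Tuple[float, float] = DEFAULT_VALID_RANGE
    scale: float = 1.0
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("linear", "sigmoid"):
            raise CalibrationError(f"unknown calibration model {self.model!r}")
        if self.scale <= 0:
            raise CalibrationError("scale must be > 0")
        lo, hi = self.valid_range
        grid = np.linspace(lo, hi, 64)
        if np.any(np.diff(self._base_ratio(grid)) <= 0):
            raise CalibrationError("calibration curve must be strictly increasing in pH")

    def _base_ratio(self, ph):
        if self.model == "linear":
            a, b = self.params
            return a * np.asarray(ph, dtype=float) + b
        return _sigmoid(ph, *self.params)

    def predict_ratio(self, ph):
        """Forward mapping: pH -> expected F490/F440 ratio (scale applied)."""
        return self.scale * self._base_ratio(ph)

    def ratio_to_ph(self, ratio):
        """Inverse mapping: ratio(s) -> (pH, out_of_range flags, valid flags).

        Non-finite ratios are rejected (pH = NaN, valid = False) and counted
        in the log; ratios mapping outside the validity range are returned
        with the out-of-range flag set, never clipped.
        """
        ratio = np.asarray(ratio, dtype=float)
        scalar = ratio.ndim == 0
        ratio = np.atleast_1d(ratio)
        valid = np.isfinite(ratio)
        n_rejected = int((~valid).sum())
        if n_rejected:
            log.warning("ratio_to_ph: rejected %d non-finite ratio samples", n_rejected)
        base = np.where(valid, ratio / self.scale, np.nan)
        if self.model == "linear":
            a, b = self.params
            ph = (base - b) / a
        else:
            lo, hi, mid, width = self.params
            arg = (base - lo) / (hi - base)
            ph = np.where(arg > 0, mid + width * np.log(np.maximum(arg, 1e-300)), np.nan)
            valid = valid & (arg > 0)
        ph = np.where(valid, ph, np.nan)
        r_lo, r_hi = self.valid_range
        oor = valid & ((ph < r_lo) | (ph > r_hi))
        if scalar:
            return float(ph[0]), bool(oor[0]), bool(valid[0])
        return ph, oor, valid

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "params": list(self.params),
                "valid_range": list(self.valid_range),
                "scale": self.scale,
                "residual_sd": self.residual_sd,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationCurve":
        d = json.loads(text)
        return cls(
            model=d["model"],
            params=tuple(d["params"]),
            valid_range=tuple(d["valid_range"]),
            scale=d.get("scale", 1.0),
            residual_sd=d.get("residual_sd", 0.0),
        )


def default_curve() -> CalibrationCurve:
    """Nominal instrument curve used by the simulator: ratio = 0.5*pH - 2."""
    return CalibrationCurve("linear", (0.5, -2.0))


def fit_calibration(
    points: Sequence[Tuple[float, float]], model: str = "linear"
) -> CalibrationCurve:
    """Least-squares fit of the standard curve to (pH, ratio) points.

    Requires >= 2 distinct pH points for the linear model, >= 4 for the
    sigmoid, and ratios monotone increasing in pH (the offending pair is
    reported otherwise).  The validity range is the span of the fitted points.
    """
    pts = sorted((float(p), float(r)) for p, r in points)
    ph = np.array([p for p, _ in pts])
    ratio = np.array([r for _, r in pts])
    if len(np.unique(ph)) < (2 if model == "linear" else 4):
        raise CalibrationError(f"too few distinct pH points for a {model} fit")
    diffs = np.diff(ratio)
    if np.any(diffs <= 0):
        i = int(np.argmax(diffs <= 0))
        raise CalibrationError(
            "calibration ratios must increase with pH; offending pair: "
            f"(pH {ph[i]}, ratio {ratio[i]}) -> (pH {ph[i + 1]}, ratio {ratio[i + 1]})"
        )
    if model == "linear":
        a, b = np.polyfit(ph, ratio, 1)
        params = (float(a), float(b))
        fitted = a * ph + b
    elif model == "sigmoid":
        p0 = (ratio.min() - 0.1, ratio.max() + 0.1, float(np.median(ph)), 0.5)
        popt, _ = optimize.curve_fit(_sigmoid, ph, ratio, p0=p0, maxfev=20000)
        params = tuple(float(v) for v in popt)
        fitted = _sigmoid(ph, *params)
    else:
        raise CalibrationError(f"unknown calibration model {model!r}")
    resid = ratio - fitted
    dof = max(1, len(ph) - len(params))
    return CalibrationCurve(
        model=model,
        params=params,
        valid_range=(float(ph.min()), float(ph.max())),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
    )


def one_point_rescale(
    curve: CalibrationCurve, measured_ratio: float, known_ph: float
) -> CalibrationCurve:
    """End-of-experiment one-point correction.

    Sets the multiplicative scale so the curve predicts ``measured_ratio``
    exactly at ``known_ph``; the shape of the mapping is unchanged.  Applying
    the same point twice is a no-op the second time.
    """
    lo, hi = curve.valid_range
    if not (lo <= known_ph <= hi):
        raise CalibrationError(
            f"known_ph {known_ph} outside curve validity range [{lo}, {hi}]"
        )
    predicted = curve._base_ratio(known_ph)
    if predicted == 0 or not np.isfinite(predicted):
        raise RescaleError(f"curve predicts ratio {predicted} at pH {known_ph}")
    return replace(curve, scale=float(measured_ratio) / float(predicted))


def ratio_to_ph(curve: CalibrationCurve, ratio):
    """Functional alias for :meth:`CalibrationCurve.ratio_to_ph`."""
    return curve.ratio_to_ph(ratio)
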