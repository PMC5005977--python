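"""Seeded end-to-end runs: simulate -> calibrate -> washout -> group statistics.

A run is described by a :class:`RunConfig` (usually loaded from YAML).  Every
run serializes its resolved configuration and seed into the output directory,
so re-running a saved config reproduces the outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .calibration import CalibrationCurve
from .errors import PhifluxError
from .presets import AMMONIUM_PRESETS, BUFFER_MODELS, SODIUM_PRESETS
from .protocols import ammonium_washout_protocol, sodium_washout_protocol
from .reproduce import fitted_default_curve
from .simulate import simulate_cohort
from .stats import ancova_slopes, anova_snk, split_bimodal, summarize_groups
from .washout import (
    AMMONIUM_BASELINE_WINDOW,
    RECOVERY_WINDOW,
    SODIUM_ACID_WINDOW,
    SODIUM_BASELINE_WINDOW,
    analyze_cohort,
    trace_to_ph,
)

log = logging.getLogger(__name__)

_EXPERIMENTS = ("ammonium", "sodium")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    experiment: str = "ammonium"  # selects protocol, preset family, windows
    cohort: Dict[str, int] = field(default_factory=dict)  # preset name -> n cells
    noise_sd: float = 0.005
    bleach_rate: float = 2e-5
    sample_interval: float = 5.0
    baseline_window: Optional[Tuple[float, float]] = None
    slope_window: Optional[Tuple[float, float]] = None
    split_group: Optional[str] = None  # apply the bimodal split to this group
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise PhifluxError(
                f"config field 'experiment': {self.experiment!r} not in {_EXPERIMENTS}"
            )
        presets = self.preset_family()
        for name in self.cohort:
            if name not in presets:
                raise PhifluxError(
                    f"config field 'cohort': unknown preset {name!r} for "
                    f"{self.experiment} experiment (have {sorted(presets)})"
                )
        for fname in ("noise_sd", "bleach_rate", "sample_interval"):
            if getattr(self, fname) < 0 or (fname == "sample_interval" and self.sample_interval <= 0):
                raise PhifluxError(f"config field {fname!r} must be positive")
        if not self.cohort:
            raise PhifluxError("config field 'cohort' must name at least one preset")
        if self.baseline_window is None:
            self.baseline_window = (
                AMMONIUM_BASELINE_WINDOW if self.experiment == "ammonium" else SODIUM_BASELINE_WINDOW
            )
        if self.slope_window is None:
            self.slope_window = (
                RECOVERY_WINDOW if self.experiment == "ammonium" else SODIUM_ACID_WINDOW
            )

    def preset_family(self) -> Dict:
        return AMMONIUM_PRESETS if self.experiment == "ammonium" else SODIUM_PRESETS

    def protocol(self):
        maker = (
            ammonium_washout_protocol if self.experiment == "ammonium" else sodium_washout_protocol
        )
        return maker(sample_interval=self.sample_interval)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = pio.load_yaml(path)
        known = {f for f in cls.__dataclass_fields__}
        for key in raw:
            if key not in known:
                raise PhifluxError(f"unknown config field {key!r}")
        for key in ("baseline_window", "slope_window"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def resolved(self) -> dict:
        d = asdict(self)
        d["baseline_window"] = list(self.baseline_window)
        d["slope_window"] = list(self.slope_window)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = {k: v for k, v in self.resolved().items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute one seeded run; writes stage outputs and returns the JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    presets = config.preset_family()
    protocol = config.protocol()

    preset_counts = [(presets[name], n) for name, n in config.cohort.items()]
    cohort = simulate_cohort(
        preset_counts,
        protocol,
        seed=config.seed,
        noise_sd=config.noise_sd,
        bleach_rate=config.bleach_rate,
    )
    pio.write_cohort_csv(cohort, out / "traces.csv", out / "truth.csv")

    curve = fitted_default_curve()
    (out / "calibration.json").write_text(curve.to_json())

    # per-cell washout analysis, buffer model per preset's cell class
    direction = "efflux" if config.experiment == "ammonium" else "production"
    results = []
    for truth, trace in zip(cohort.truths, cohort.traces):
        model = BUFFER_MODELS[truth.preset_name]
        pt = trace_to_ph(trace, curve)
        df = analyze_cohort(
            [pt],
            model,
            config.baseline_window,
            [config.slope_window],
            groups=[truth.sub_label or truth.preset_name],
            flux_direction=direction,
        )
        results.append(df)
    results_df = pd.concat(results, ignore_index=True)
    results_df.to_csv(out / "washout_results.csv", index=False)

    # group-level statistics
    baselines_by_group: Dict[str, List[float]] = {}
    for _, row in results_df.iterrows():
        baselines_by_group.setdefault(row["group"], []).append(row["baseline_ph"])

    split_info = None
    if config.split_group:
        members = results_df[
            results_df["group"].str.startswith(config.split_group)
        ]
        if len(members) >= 4:
            split = split_bimodal(members["baseline_ph"].to_numpy())
            labels = np.where(split.high_mask, f"{config.split_group}_high", f"{config.split_group}_low")
            baselines_by_group = {
                g: v
                for g, v in baselines_by_group.items()
                if not g.startswith(config.split_group)
            }
            for lab, val in zip(labels, members["baseline_ph"]):
                baselines_by_group.setdefault(lab, []).append(val)
            split_info = {
                "threshold": split.threshold,
                "n_high": int(split.high_mask.sum()),
                "n_low": int((~split.high_mask).sum()),
            }

    summary = summarize_groups(baselines_by_group, config.baseline_window)
    summary.to_csv(out / "group_summary.csv", index=False)

    stats_block: dict = {}
    if len(baselines_by_group) >= 3 and all(len(v) >= 2 for v in baselines_by_group.values()):
        snk = anova_snk(baselines_by_group)
        snk.table.to_csv(out / "pairwise_tests.csv", index=False)
        stats_block["anova_F"] = snk.anova_f
        stats_block["anova_p"] = snk.anova_p

    report = {
        "seed": config.seed,
        "config": config.resolved(),
        "config_hash": config.config_hash(),
        "python": sys.version.split()[0],
        "n_cells": len(cohort),
        "groups": summary.to_dict(orient="records"),
        "split": split_info,
        "stats": stats_block,
        "outputs": [
            "traces.csv",
            "truth.csv",
            "calibration.json",
            "washout_results.csv",
            "group_summary.csv",
        ],
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    log.info("pipeline run %s complete: %d cells", config.config_hash(), len(cohort))
    return report
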