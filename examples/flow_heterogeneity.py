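"""2-NBDG glucose-uptake distributions: gating, histograms, heterogeneity.

Simulates flow-cytometry events for nMEC, MINO and Met1 with realistic
contamination, depletes dead/hematopoietic/endothelial events, builds
256-bin unit-area histograms, and scores each distribution with the
one- vs two-component mixture delta-BIC.
"""

import numpy as np

from phiflux import (
    SODIUM_PRESETS,
    apply_gates,
    default_depletion_gates,
    heterogeneity_score,
    simulate_flow_events,
    unit_area_histogram,
)

contamination = {"DAPI": 0.05, "CD45": 0.08, "TER119": 0.03, "CD31": 0.02}

print(f"{'sample':6s} {'kept':>6s} {'mode':>8s} {'IQR(log10)':>11s} {'dBIC':>8s} {'verdict'}")
for name, seed in [("nMEC", 1), ("MINO", 2), ("Met1", 3)]:
    events = simulate_flow_events([(SODIUM_PRESETS[name], 20_000)], contamination, seed=seed)
    kept, attrition = apply_gates(events, default_depletion_gates())
    hist = unit_area_histogram(kept["NBDG"])
    mode = 10 ** hist.bin_centers[np.argmax(hist.density)]
    mix = heterogeneity_score(kept["NBDG"], seed=0)
    verdict = "bimodal" if mix.n_components == 2 else "unimodal"
    print(f"{name:6s} {len(kept):6d} {mode:8.0f} {mix.iqr_log10:11.3f} {mix.delta_bic:8.1f} {verdict}")

# Met1 peaks above 10^3 fluorescence units (high uptake), nMEC below it;
# MINO has the widest distribution and a positive delta-BIC: two overlapping
# uptake populations rather than one.
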