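"""Render a dual-channel image stack and recover the traces by ROI extraction.

Cells are bright disks over a constant background, one frame per (time,
channel).  ROI means minus the background-ROI estimate reproduce the input
fluorescence traces, closing the image-analysis loop.
"""

import numpy as np

from phiflux import (
    SODIUM_PRESETS,
    auto_roi_map,
    extract_roi_traces,
    render_image_stack,
    simulate_cohort,
    sodium_washout_protocol,
)

protocol = sodium_washout_protocol()
cohort = simulate_cohort([(SODIUM_PRESETS["nMEC"], 3)], protocol, seed=4)

roi_map = auto_roi_map([t.cell_id for t in cohort.traces], field_shape=(64, 64), radius=5)
stack = render_image_stack(cohort.traces, roi_map, background=50.0, noise_sd=0.5, seed=5)
print(f"stack shape (frames, channels, H, W): {stack.shape}")

recovered = extract_roi_traces(
    stack, roi_map, times=cohort.traces[0].times, phase_labels=cohort.traces[0].phase_labels
)
for orig, rec in zip(cohort.traces, recovered):
    err = np.max(np.abs((rec.i490 - rec.background490) - orig.i490))
    print(f"{orig.cell_id}: max |I490 error| after background subtraction = {err:.2f} "
          f"(signal ~ {orig.i490.mean():.0f})")

# Extraction errors are at the shot-noise level, far below the signal:
# the imaging step neither biases nor distorts the downstream pH analysis.
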