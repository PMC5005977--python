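# phiflux

Single-cell intracellular pH (pH_i) regulation and glucose-uptake
heterogeneity in mouse mammary cells — normal mammary epithelial cells
(nMEC), the MINO precancer model of DCIS, and Met1 / PyVmT cancer cells.

`phiflux` re-implements, as a tested pipeline, the quantitative chain behind
this kind of live-cell physiology study:

1. **BCECF ratio calibration** — dual-excitation (490/440 nm) fluorescence
   ratios mapped to pH through a five-point high-K⁺/nigericin standard curve
   over pH 6.2–8.2, with a one-point end-of-experiment drift correction.
2. **Washout analysis** — baseline pH_i windows, OLS slopes of acidification
   (sodium washout: NHE1 blocked, slope reports endogenous proton
   production) and recovery (ammonium-prepulse washout: slope reports NHE1
   acid extrusion), converted to fluxes via the intrinsic buffer capacity:

   J (mM·min⁻¹) = ß(pH_i) · |dpH_i/dt| · 60,  ß(pH_i) = m·pH_i + b

   with measured class-specific ß equations (e.g. ß = −52.95·pH_i + 400 for
   nMEC, which gives 29 mM/pH at pH 7).
3. **Cohort statistics** — exact 1-D two-means splitting of bimodal baseline
   distributions (the MINO high/low separation), per-timepoint Welch t-tests,
   ANCOVA on regression slopes, and one-way ANOVA with Student-Newman-Keuls
   post-hoc comparisons.
4. **2-NBDG flow cytometry** — DAPI/CD45/TER119/CD31 depletion gating,
   256-bin unit-area histograms on a log₁₀ axis, and a one- vs two-component
   Gaussian-mixture ΔBIC score for uptake heterogeneity.

No experimental data are required: a **synthetic physiology generator**
integrates a per-cell proton budget, dpH/dt = (J_NHE − J_prod + J_NH4) /
(60·ß(pH)), under the superfusion protocols (HEPES-Ringer's baseline,
20 mM NH₄Cl prepulse, Na⁺-free washout, Na⁺ re-addition, nigericin
calibration), renders noisy dual-channel fluorescence, and emulates flow
events — so every stage of the analysis is testable against ground truth.

## Worked example

`examples/` holds one short script per capability. For instance, per-cell
proton-flux quantification on a synthetic Met1 ammonium washout
(`python examples/proton_flux_analysis.py`):

```
baseline pH_i (250-400 s):   7.061 +/- 0.0040
recovery slope (1400-1800 s): 7.958e-04 pH/s  (R^2 0.959)
initial recovery slope:       9.895e-04 pH/s
buffer capacity at pH 6.43: 45.0 mM/pH
initial NHE1 efflux:          2.67 mM/min
```

The baseline window mean recovers the cell's resting pH_i; the 1400–1800 s
regression slope is the standard recovery-rate readout (for Met1,
7.678 × 10⁻⁴ pH/s at the preset mean); multiplying the steeper initial slope
by the buffer capacity at the prevailing pH gives the early NHE1 acid-efflux
flux in mM/min.

And the MINO subpopulation split (`python examples/mino_subpopulations.py`):

```
split threshold: pH 7.104
MINO high: n=  9, mean 7.210
MINO low:  n= 59, mean 6.954
```

The exact two-means split separates the 68-cell MINO cohort at pH ≈ 7.10
into an alkaline, cancer-like subpopulation (mean ≈ 7.21, like Met1) and an
acidic, normal-like one (mean ≈ 6.97, like nMEC).

A thin CLI mirrors the stages
(`phiflux simulate | calibrate | washout | stats | flow | run |
reproduce-targets`); see `phiflux --help`.

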