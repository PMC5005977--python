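# Methods

## The measurement chain

`phiflux` models the standard single-cell pH_i workflow: BCECF-loaded cells
are superfused in a chamber while dual-excitation fluorescence (490/440 nm
ex, 535 nm em) is imaged; the background-corrected F490/F440 ratio is mapped
to pH through a nigericin/high-K⁺ standard curve; windows of the calibrated
trace yield baseline means and acidification/recovery slopes; and slopes
become proton fluxes through the intrinsic buffer capacity,
J = ß(pH_i)·|dpH_i/dt|·60 (mM/min, with slopes kept in pH/s and the factor
60 applied exactly once).

Two superfusion experiments are built in:

* **Sodium washout** — HR (HEPES Ringer's) 0–200 s, then Na⁺-free solution
  200–900 s. With bath Na⁺ removed, NHE1 cannot extrude acid, so the
  acidification slope reports endogenous proton production. Baseline is the
  first 200 s; the acidification regression uses the Na⁺-free phase.
* **Ammonium-prepulse washout** — HR 0–400 s, HR + 20 mM NH₄Cl 400–700 s,
  Na⁺-free 700–1300 s, HR 1300–1800 s. The prepulse acid-loads the cell;
  re-adding Na⁺ lets NHE1 recover pH_i, and the 1400–1800 s regression slope
  reports extrusion activity. Baseline is 250–400 s. The phase timings
  extend the tersely stated 2-min HR loading so that both printed analysis
  windows (250–400 s and 1400–1800 s) fall inside single phases.

Windows are half-open `[t0, t1)`; protocol phases likewise, with the final
phase owning the protocol end point. Phase boundaries snap to the 5 s
sampling grid. A window crossing a phase boundary is an error, not a silent
truncation.

## Generative model

Each simulated cell integrates a proton budget through its linear intrinsic
buffer capacity:

    dpH/dt = (J_NHE − J_prod + J_NH4) / (60 · ß(pH)),   ß(pH) = m·pH + b

* **J_prod** (mM/min): constant endogenous acid production.
* **J_NHE = g·max(0, pH_set − pH)** when bath Na⁺ is present, else 0. Linear
  kinetics below the set point are the simplest form that reproduces faster
  recovery at more acidic pH_i; the gain g (mM/min per pH) is the phenotype's
  extrusion capacity. Each cell's set point is shifted with its drawn
  baseline (pH_set = baseline + J_prod/g), so cells rest at flux balance
  until perturbed — without this, every cell would drift toward a common
  attractor and between-cell baseline structure would decay.
* **Ammonium prepulse** (two-jump weak-base approximation): on NH₄Cl
  application an instantaneous alkaline jump (0.015 pH/mM, i.e. +0.30 at
  20 mM); during the pulse, internal ammonium accumulates with τ = 180 s
  while NH₄⁺ entry acid-loads at 0.008 mM/min per mM; on removal, an
  instantaneous acid jump of 0.045 pH per mM accumulated. Full NH₃/NH₄⁺
  equilibrium chemistry is deliberately out of scope: the analysis only
  needs a realistic acid load. The alkaline jump is clipped so ß stays
  ≥ 5 mM/pH — the measured linear ß equations reach zero within the
  alkaline range (Met1's at pH 7.60), which is a limit of the linear model,
  not physiology; without the clamp an alkaline cell would cross ß ≤ 0 and
  the integrator (correctly) raises a physiology error.
* **Nigericin phase**: pH_i is clamped to the known bath pH, enabling
  one-point calibration simulations.

Integration is explicit Euler at dt = sample_interval/10 (0.5 s by default);
the dynamics' fastest time constants are minutes, and a 10× finer step
changes trajectories by < 5 × 10⁻⁵ pH (checked in the tests). Buffer
positivity is enforced at every step.

**Rendering**: the 440 nm channel is a pH-independent reference
(1000 units); the 490 nm channel is the calibration curve's predicted ratio
times that reference. Both share one exponential bleach factor (default
2 × 10⁻⁵ s⁻¹, ratio-invariant in expectation) and receive independent
multiplicative Gaussian noise (default 0.5% per channel, giving ~0.02 pH
per-sample noise after inversion — typical of photon-rich ratio imaging).
Samples whose true pH leaves the curve's validity range are flagged, never
clipped.

**Flow cytometry**: 2-NBDG intensity is log-normal per phenotype (log₁₀
means 2.7 for nMEC, 3.25 for Met1; the MINO preset mixes both with wider
spread), on a fluorescence axis where the 10³ landmark separates low from
high uptake. Marker channels (DAPI/CD45/TER119/CD31) are bimodal by
construction (log₁₀ modes 1.5/3.5); contaminant events are positive on
exactly their marker, and default gates sit at the valley midpoint
(10^2.5). Real instrument gates, compensation and doublet discrimination
are out of scope — the test surface is the pipeline, not the cytometer.

## Parameter provenance

* **Baseline distributions**: preset means are the printed group means
  (ammonium cohorts: nMEC 6.94, Met1 7.06, PyVmT 7.28; sodium/baseline
  cohorts: nMEC 6.90, Met1 7.18, MINO high 7.21, MINO low 6.97). Between-cell
  SD is reconstructed as SEM·√n using each figure's stated replication unit
  — cells for the ammonium cohorts (e.g. nMEC 0.03·√11 ≈ 0.10), coverslips
  for the sodium/baseline cohorts (e.g. MINO low 0.02·√7 ≈ 0.053). Treating
  the 59-cell count as the unit there would give SD ≈ 0.15, which is
  physiologically implausible for resting pH_i and incompatible with the
  observed clean two-group separation; SEMs over independent replicates
  (coverslips) are also the reporting convention.
* **MINO mixture**: 9:59 high:low weights, matching the observed counts in
  a 68-cell cohort.
* **Buffer capacities**: the printed equations are used directly
  (nMEC −52.95·pH + 400; Met1 −38.55·pH + 293; MINO −29.01·pH + 227; PyVmT
  aliases Met1, as the original flux computation did). At pH 7 the nMEC
  equation gives 29.35 → 29 mM/pH; the Met1 and MINO equations evaluate to
  23.15 and 23.93, which do not match the rounded values printed alongside
  them (24 and 23.5) — the package trusts the equations and records the
  discrepancy here.
* **Rates**: J_prod per phenotype is solved (offline, then frozen) so a
  noiseless simulation at the preset-mean baseline reproduces the printed
  sodium-washout regression slopes (−0.617 × 10⁻⁴ nMEC, −2.037 × 10⁻⁴ Met1,
  −2.74 × 10⁻⁴ MINO high, −1.471 × 10⁻⁴ MINO low, all pH/s over 200–900 s);
  the NHE1 gain is then solved against the printed 1400–1800 s recovery
  slopes (1.721 × 10⁻⁴ nMEC, 7.678 × 10⁻⁴ Met1, 1.008 × 10⁻³ PyVmT). The
  recovery slope is non-monotone in g (a very fast recovery finishes before
  the window); the solution on the rising branch is taken, matching the
  visual impression of recovery still in progress at 1800 s. MINO gains are
  unconstrained by any printed recovery slope and are set to 3.5 mM/min/pH
  (a realistic ~5 min recovery). The washout acid-jump coefficient (0.045
  pH/mM) was chosen so the acid load (pH_min ≈ 6.4–6.5) resembles the
  published traces and leaves the printed recovery slopes reachable.
* **Group sizes**: ammonium cohorts 11/5/10 (nMEC/Met1/PyVmT); the Welch
  comparison uses the stated 3 vs 6 coverslips at the cells-per-coverslip
  ratios of the baseline study (≈13 for nMEC, ≈18 for Met1 → 39 vs 108
  cells); baseline cohorts 120/145/68.

## Analysis choices

* **Calibration**: default model is linear in pH over 6.2–8.2 (adequate near
  the BCECF pK; local-linear calibration is the convention for this
  protocol); a 4-parameter logistic is available. The one-point
  end-of-experiment correction is a multiplicative ratio scale, not an
  additive pH offset, because instrument drift acts multiplicatively on
  intensities.
* **QC gates**: a ratio sample is invalid if its corrected denominator is
  ≤ 0; a trace fails if > 1% of samples are invalid; slope fits need ≥ 5
  samples, baselines ≥ 3. These thresholds are artifact choices made
  explicit for reproducibility.
* **MINO split**: exact 1-D two-means — exhaustive scan of the n−1
  thresholds minimizing pooled within-group sum of squares, ties broken
  toward the lower threshold. Objective, deterministic, and verified against
  a brute-force oracle in the tests.
* **Welch tests** are per-timepoint and uncorrected (a Benjamini–Hochberg
  option exists, default off), on cell-level replicates by default.
* **SNK** uses studentized-range critical values with the one-way ANOVA
  error df, harmonic mean n for unequal groups, and standard step-down
  shielding (a non-significant span protects all nested pairs).
* **Repeated-measures comparisons** are implemented as one-way ANOVA on
  per-cell window means: only window-mean comparisons are reported, so the
  repeated dimension is collapsed by averaging.
* **"Initial flux"** is computed over the first 60 s of the recovery phase,
  distinct from the 1400–1800 s regression window: the published initial
  flux values exceed ß × (1400–1800 s slope), implying a steeper early
  window. This is recorded as a convention, not asserted as a target.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analysis assumes:
between-cell baseline dispersion, phase-locked acidification/recovery
kinetics consistent with the printed slopes, ratio-metric noise and bleach,
mixture structure in MINO, and marker-separable contamination in flow.
It does not emulate focus drift, cell movement or segmentation error,
heteroscedastic photon noise, coverslip-level batch effects (cells are
exchangeable within a cohort), bicarbonate/CO₂ buffering, or mechanistic
GLUT1 transport. Passing tests therefore demonstrate that the analysis
recovers known ground truth under idealized but realistically parameterized
conditions — not that it is robust to every artifact of live-cell imaging.

## Problem sizes

Replicated experiments use 20 seeded replicates at the observed group sizes
(up to 145 cells × 361 samples per replicate); null-calibration suites use
100–200 replicates of small synthetic datasets. These sizes give stable
medians and binomial intervals while keeping the whole suite fast on a
single CPU.

## Known limitations

* Coverslip nesting is not modeled (no mixed-effects structure); SEMs and
  tests treat cells as independent, as the original analysis did.
* The linear ß(pH) equations are extrapolated outside 6.2–7.4 with a warning
  and a positivity guard; they are not valid near their zero crossings.
* The two-jump ammonium approximation has no independent intracellular
  ammonium data to validate against; its parameters are plausibility
  choices.
* The mixture ΔBIC heterogeneity score is an added, interpretive statistic
  operationalizing a qualitative claim; it is flagged as such in the API
  docs.
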