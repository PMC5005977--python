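"""Simulator physics: steady states, flux bookkeeping, rendering, cohort structure."""

import numpy as np
import pytest
from scipy import stats as sps

from phiflux.errors import PhysiologyError, ProtocolError
from phiflux.presets import (
    AMMONIUM_PRESETS,
    BUFFER_MODELS,
    SODIUM_PRESETS,
    AmmoniumPulseParams,
)
from phiflux.protocols import PhaseSpec, SuperfusionProtocol
from phiflux.simulate import (
    render_fluorescence,
    simulate_cohort,
    simulate_flow_events,
    simulate_ph_trajectory,
)
from phiflux.washout import buffer_capacity

from conftest import make_preset


def hr_only_protocol(duration=600.0):
    return SuperfusionProtocol(
        phases=(PhaseSpec("HR", 0.0, duration, na_present=True),), sample_interval=5.0
    )


def na_free_protocol(duration=600.0, baseline_s=100.0):
    return SuperfusionProtocol(
        phases=(
            PhaseSpec("HR", 0.0, baseline_s, na_present=True),
            PhaseSpec("NA_FREE", baseline_s, baseline_s + duration, na_present=False),
        ),
        sample_interval=5.0,
    )


class TestTrajectory:
    def test_steady_state_when_production_balances_extrusion(self):
        # J_prod = g*(pH_set - pH0) exactly -> pH constant under HR
        preset = make_preset(baseline=7.0, j_prod=0.2, gain=2.0)
        trace = simulate_ph_trajectory(preset, hr_only_protocol(), baseline=7.0)
        assert np.allclose(trace.ph, 7.0, atol=1e-12)

    def test_sodium_free_phase_is_nonincreasing(self):
        preset = make_preset(baseline=7.0, j_prod=0.2, gain=2.0)
        trace = simulate_ph_trajectory(preset, na_free_protocol(), baseline=7.0)
        na_free = trace.phase_labels == "NA_FREE"
        diffs = np.diff(trace.ph[na_free])
        assert np.all(diffs <= 0)
        assert trace.ph[na_free][-1] < 7.0  # strictly acidifying overall

    def test_acidification_rate_matches_fine_step_ode_oracle(self):
        # nMEC buffer model: implied J_prod = ss(pH)*|dpH/dt|*60 must agree
        # with an independent Euler integration at 10x finer step.
        preset = make_preset(baseline=6.9, j_prod=0.13248, gain=1.25, buffer_class="nMEC")
        protocol = na_free_protocol()
        coarse = simulate_ph_trajectory(preset, protocol, baseline=6.9)
        fine = simulate_ph_trajectory(preset, protocol, baseline=6.9, dt=0.05)
        assert np.allclose(coarse.ph, fine.ph, atol=5e-5)
        # instantaneous rate at mid-phase recovers J_prod
        mask = (coarse.times >= 300) & (coarse.times <= 400)
        t, y = coarse.times[mask], coarse.ph[mask]
        slope = sps.linregress(t, y).slope
        beta = buffer_capacity(BUFFER_MODELS["nMEC"], float(y.mean()))
        assert beta * abs(slope) * 60 == pytest.approx(0.13248, rel=0.01)

    def test_flux_bookkeeping_over_sodium_free_interval(self):
        # integral of ss(pH) dpH equals -J_prod * dt (mM) within ODE tolerance
        preset = make_preset(baseline=7.1, j_prod=0.3, gain=3.0, buffer_class="Met1")
        trace = simulate_ph_trajectory(preset, na_free_protocol(), baseline=7.1)
        na_free = trace.phase_labels == "NA_FREE"
        t, ph = trace.times[na_free], trace.ph[na_free]
        beta_mid = BUFFER_MODELS["Met1"].beta(0.5 * (ph[1:] + ph[:-1]))
        acid_delivered = -(beta_mid * np.diff(ph)).sum()  # mM
        expected = preset.proton_production * (t[-1] - t[0]) / 60.0
        assert acid_delivered == pytest.approx(expected, rel=0.005)

    def test_ammonium_pulse_shape(self, ammonium_protocol):
        preset = AMMONIUM_PRESETS["Met1"]
        trace = simulate_ph_trajectory(preset, ammonium_protocol, baseline=7.06)
        ph_at = lambda t: trace.ph[np.searchsorted(trace.times, t)]
        assert ph_at(400) > 7.06 + 0.2  # alkaline jump on NH4 application
        assert ph_at(700) < ph_at(405)  # acid creep during the pulse
        assert ph_at(705) < 7.06 - 0.3  # acid jump on washout
        assert ph_at(1795) > ph_at(1400)  # recovery after Na re-addition

    def test_nigericin_phase_clamps_ph(self):
        protocol = SuperfusionProtocol(
            phases=(
                PhaseSpec("HR", 0.0, 100.0, na_present=True),
                PhaseSpec("HIGH_K_NIGERICIN", 100.0, 200.0, na_present=False, known_ph=7.0),
            ),
            sample_interval=5.0,
        )
        trace = simulate_ph_trajectory(make_preset(baseline=7.3), protocol, baseline=7.3)
        assert np.all(trace.ph[trace.phase_labels == "HIGH_K_NIGERICIN"] == 7.0)

    def test_beta_zero_raises_physiology_error(self):
        # huge alkaline jump drives Met1 ss toward zero without the clamp
        pulse = AmmoniumPulseParams(alkaline_jump_per_mM=0.05, beta_floor=-50.0)
        protocol = SuperfusionProtocol(
            phases=(
                PhaseSpec("HR", 0.0, 100.0, na_present=True),
                PhaseSpec("HR_NH4", 100.0, 400.0, na_present=True, nh4_mM=20.0),
            ),
            sample_interval=5.0,
        )
        preset = make_preset(baseline=7.2, j_prod=0.0, gain=0.0, buffer_class="Met1")
        with pytest.raises((PhysiologyError, ValueError)):
            simulate_ph_trajectory(preset, protocol, baseline=7.2, pulse=pulse)

    def test_non_contiguous_protocol_rejected(self):
        with pytest.raises(ProtocolError):
            SuperfusionProtocol(
                phases=(
                    PhaseSpec("HR", 0.0, 100.0, na_present=True),
                    PhaseSpec("NA_FREE", 150.0, 300.0, na_present=False),
                )
            )


class TestRender:
    def test_zero_noise_round_trip(self, curve):
        preset = make_preset(baseline=6.9, j_prod=0.13, gain=1.25)
        truth = simulate_ph_trajectory(preset, na_free_protocol(), baseline=6.9)
        trace = render_fluorescence(truth, curve, noise_sd=0.0, bleach_rate=0.0)
        ph, oor, valid = curve.ratio_to_ph(trace.i490 / trace.i440)
        assert valid.all() and not oor.any()
        assert np.allclose(ph, truth.ph, atol=1e-6)

    def test_bleach_cancels_in_ratio(self, curve):
        preset = make_preset(baseline=7.0)
        truth = simulate_ph_trajectory(preset, hr_only_protocol(), baseline=7.0)
        trace = render_fluorescence(truth, curve, noise_sd=0.0, bleach_rate=5e-4)
        assert trace.i440[-1] < 0.8 * trace.i440[0]  # channels really decay
        ph, _, _ = curve.ratio_to_ph(trace.i490 / trace.i440)
        assert np.allclose(ph, truth.ph, atol=1e-4)

    def test_noise_propagation_matches_delta_method(self, curve):
        # Monte-Carlo SD of recovered pH vs first-order error propagation:
        # sd_pH ~ ratio * sqrt(2) * sigma / slope for the linear curve.
        preset = make_preset(baseline=7.0)
        truth = simulate_ph_trajectory(preset, hr_only_protocol(), baseline=7.0)
        sigma = 0.02
        recovered = []
        for seed in range(500):
            tr = render_fluorescence(truth, curve, noise_sd=sigma, bleach_rate=0.0, seed=seed)
            ph, _, _ = curve.ratio_to_ph(tr.i490 / tr.i440)
            recovered.append(ph)
        recovered = np.asarray(recovered)
        ratio0 = float(curve.predict_ratio(7.0))
        predicted_sd = ratio0 * np.sqrt(2) * sigma / 0.5
        assert abs(recovered.mean() - 7.0) < 0.005  # unbiased to first order
        assert np.std(recovered) == pytest.approx(predicted_sd, rel=0.15)

    def test_out_of_range_ph_flagged_not_clipped(self, curve):
        protocol = SuperfusionProtocol(
            phases=(
                PhaseSpec("HR", 0.0, 100.0, na_present=True),
                PhaseSpec("HIGH_K_NIGERICIN", 100.0, 200.0, na_present=False, known_ph=8.4),
            ),
            sample_interval=5.0,
        )
        truth = simulate_ph_trajectory(make_preset(baseline=7.0), protocol, baseline=7.0)
        trace = render_fluorescence(truth, curve, noise_sd=0.0, bleach_rate=0.0)
        clamped = truth.phase_labels == "HIGH_K_NIGERICIN"
        assert trace.oor_flags[clamped].all()
        assert not trace.oor_flags[~clamped].any()


class TestCohort:
    def test_seed_determinism(self, sodium_protocol):
        a = simulate_cohort([(SODIUM_PRESETS["nMEC"], 5)], sodium_protocol, seed=42)
        b = simulate_cohort([(SODIUM_PRESETS["nMEC"], 5)], sodium_protocol, seed=42)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.i490, tb.i490)
            np.testing.assert_array_equal(ta.i440, tb.i440)
        c = simulate_cohort([(SODIUM_PRESETS["nMEC"], 5)], sodium_protocol, seed=43)
        assert not np.array_equal(a.traces[0].i490, c.traces[0].i490)

    def test_single_cell_cohort_matches_standalone_run(self, sodium_protocol, curve):
        cohort = simulate_cohort([(SODIUM_PRESETS["Met1"], 1)], sodium_protocol, seed=7)
        child = np.random.SeedSequence(7).spawn(1)[0]
        traj_ss, render_ss = child.spawn(2)
        truth = simulate_ph_trajectory(SODIUM_PRESETS["Met1"], sodium_protocol, seed=traj_ss)
        trace = render_fluorescence(truth, curve, seed=render_ss)
        np.testing.assert_array_equal(cohort.truths[0].ph, truth.ph)
        np.testing.assert_array_equal(cohort.traces[0].i490, trace.i490)

    def test_group_mean_baselines_recover_presets(self, ammonium_protocol):
        counts = [("nMEC", 11), ("Met1", 5), ("PyVmT", 10)]
        cohort = simulate_cohort(
            [(AMMONIUM_PRESETS[n], k) for n, k in counts], ammonium_protocol, seed=0
        )
        for name, k in counts:
            preset = AMMONIUM_PRESETS[name]
            truths = [t for t in cohort.truths if t.preset_name == name]
            assert len(truths) == k
            mean = np.mean([t.true_baseline for t in truths])
            sem = preset.ph_baseline_sd / np.sqrt(k)
            assert abs(mean - preset.ph_baseline_mean) < 2 * sem + 1e-9

    def test_mixture_fraction_within_binomial_interval(self, sodium_protocol):
        n = 500
        cohort = simulate_cohort([(SODIUM_PRESETS["MINO"], n)], sodium_protocol, seed=3)
        n_high = sum(t.sub_label == "MINO_high" for t in cohort.truths)
        p = 9 / 68
        lo, hi = sps.binom.interval(0.95, n, p)
        assert lo <= n_high <= hi

    def test_mixture_marginal_matches_oracle_sampler(self):
        # pooled baseline distribution == weighted component mixture (KS test)
        preset = SODIUM_PRESETS["MINO"]
        rng = np.random.default_rng(11)
        draws = []
        from phiflux.simulate import _draw_cell

        for _ in range(5000):
            _, _, b = _draw_cell(preset, rng)
            draws.append(b)
        oracle_rng = np.random.default_rng(99)
        comps = preset.components()
        weights = [w for w, _ in comps]
        idx = oracle_rng.choice(len(comps), size=5000, p=weights)
        means = np.array([c.ph_baseline_mean for _, c in comps])[idx]
        sds = np.array([c.ph_baseline_sd for _, c in comps])[idx]
        oracle = oracle_rng.normal(means, sds)
        assert sps.ks_2samp(np.asarray(draws), oracle).pvalue > 0.01


class TestFlowEvents:
    def test_clean_events_pass_all_gates(self):
        from phiflux.flow import apply_gates, default_depletion_gates

        events = simulate_flow_events([(SODIUM_PRESETS["Met1"], 2000)], seed=0)
        kept, attrition = apply_gates(events, default_depletion_gates())
        assert len(kept) == 2000
        assert all(v == 0 for v in attrition.values())

    def test_spiked_contamination_recovers_binomial_fraction(self):
        from phiflux.flow import apply_gates, default_depletion_gates

        n = 10_000
        events = simulate_flow_events(
            [(SODIUM_PRESETS["Met1"], n)], contamination={"CD45": 0.20}, seed=1
        )
        kept, _ = apply_gates(events, default_depletion_gates())
        lo, hi = sps.binom.interval(0.95, n, 0.80)
        assert lo <= len(kept) <= hi
        assert not (kept["truth_label"] == "CD45+").any()

    def test_met1_modal_fluorescence_above_1e3(self):
        from phiflux.flow import unit_area_histogram

        events = simulate_flow_events([(SODIUM_PRESETS["Met1"], 20_000)], seed=2)
        hist = unit_area_histogram(events["NBDG"])
        mode_log10 = hist.bin_centers[np.argmax(hist.density)]
        assert mode_log10 > 3.0

    def test_contamination_validation(self):
        with pytest.raises(ValueError):
            simulate_flow_events(
                [(SODIUM_PRESETS["Met1"], 10)], contamination={"CD45": 0.6, "DAPI": 0.5}
            )
        with pytest.raises(ValueError):
            simulate_flow_events([(SODIUM_PRESETS["Met1"], 10)], contamination={"GFP": 0.1})
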