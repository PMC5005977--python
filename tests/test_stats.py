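"""Bimodal splitting, Welch tests, ANCOVA, and SNK multiple comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from phiflux.errors import SplitError
from phiflux.presets import SODIUM_PRESETS
from phiflux.simulate import _draw_cell
from phiflux.stats import ancova_slopes, anova_snk, pointwise_welch, split_bimodal


def brute_force_split_ss(x):
    """Independent oracle: minimum pooled within-group SS over all thresholds."""
    xs = np.sort(np.asarray(x, dtype=float))
    best = np.inf
    for k in range(1, len(xs)):
        lo, hi = xs[:k], xs[k:]
        ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        best = min(best, ss)
    return best


class TestSplitBimodal:
    def test_separated_clusters(self):
        res = split_bimodal([6.90, 6.95, 7.20, 7.25])
        assert res.labels.tolist() == ["low", "low", "high", "high"]
        assert 6.95 < res.threshold <= 7.20

    def test_threshold_separates_groups_exactly(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(6.95, 0.05, 30), rng.normal(7.25, 0.05, 10)])
        res = split_bimodal(x)
        assert x[res.high_mask].min() >= res.threshold
        assert x[~res.high_mask].max() < res.threshold

    def test_matches_exhaustive_oracle_on_random_inputs(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = rng.integers(4, 100)
            x = rng.normal(7.0, 0.15, n)
            res = split_bimodal(x)
            assert res.within_group_variance * n == pytest.approx(
                brute_force_split_ss(x), rel=1e-9, abs=1e-12
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=6.0, max_value=8.0, allow_nan=False), min_size=4, max_size=40)
    )
    def test_objective_is_global_minimum_property(self, values):
        res = split_bimodal(values)
        assert res.within_group_variance * len(values) <= brute_force_split_ss(values) + 1e-9

    def test_recovers_generating_labels_on_mino_like_cohorts(self):
        # 11 baselines per replicate drawn 6 high / 5 low; the split should
        # recover the generating labels in >= 10/11 cells (median over reps)
        high, low = SODIUM_PRESETS["MINO_high"], SODIUM_PRESETS["MINO_low"]
        rng = np.random.default_rng(31)
        correct = []
        for _ in range(100):
            truth = np.array([1] * 6 + [0] * 5)
            vals = np.where(
                truth,
                rng.normal(high.ph_baseline_mean, high.ph_baseline_sd, 11),
                rng.normal(low.ph_baseline_mean, low.ph_baseline_sd, 11),
            )
            res = split_bimodal(vals)
            correct.append((res.high_mask == truth.astype(bool)).sum())
        assert np.median(correct) >= 10

    def test_too_few_cells(self):
        with pytest.raises(SplitError):
            split_bimodal([6.9, 7.0, 7.1])


class TestPointwiseWelch:
    def test_hand_computed_single_timepoint(self):
        a = np.array([[6.9], [7.0], [7.1]])
        b = np.array([[7.2], [7.3], [7.4]])
        res = pointwise_welch(a, b, np.array([0.0]))
        t = (6.9 + 7.0 + 7.1) / 3 - (7.2 + 7.3 + 7.4) / 3
        assert res.p_values[0] == pytest.approx(0.021, abs=0.002)
        # reference Welch statistic: t = -0.3 / sqrt(0.01/3 + 0.01/3)
        assert t / np.sqrt(0.01 / 3 + 0.01 / 3) == pytest.approx(-3.674, abs=0.001)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(7.0, 0.05, size=(5, 30))
        res = pointwise_welch(a, a.copy(), 5.0 * np.arange(30))
        assert np.all(res.p_values > 0.99)
        assert res.frac_significant == 0.0

    def test_degenerate_timepoints_excluded_and_counted(self):
        a = np.tile([7.0, 7.1], (3, 1)).astype(float)
        b = np.tile([7.0, 7.3], (3, 1)).astype(float)
        b[:, 1] += np.array([0.0, 0.01, -0.01])
        res = pointwise_welch(a, b, np.array([0.0, 5.0]))
        assert np.isnan(res.p_values[0]) and res.n_excluded == 1
        assert np.isfinite(res.p_values[1])

    def test_invariant_under_common_affine_transform(self):
        rng = np.random.default_rng(9)
        a = rng.normal(6.9, 0.05, size=(6, 20))
        b = rng.normal(7.1, 0.08, size=(4, 20))
        times = 5.0 * np.arange(20)
        p1 = pointwise_welch(a, b, times).p_values
        p2 = pointwise_welch(3.0 * a - 10.0, 3.0 * b - 10.0, times).p_values
        assert np.allclose(p1, p2)

    def test_bh_correction_is_conservative(self):
        rng = np.random.default_rng(10)
        a = rng.normal(7.0, 0.05, size=(6, 40))
        b = rng.normal(7.02, 0.05, size=(6, 40))
        times = 5.0 * np.arange(40)
        raw = pointwise_welch(a, b, times)
        bh = pointwise_welch(a, b, times, correction="bh")
        finite = np.isfinite(raw.p_values)
        assert np.all(bh.p_values[finite] >= raw.p_values[finite] - 1e-12)


class TestAncova:
    def test_f_equals_squared_t_for_two_groups(self):
        rng = np.random.default_rng(4)
        t = np.tile(np.arange(30, dtype=float), 2)
        g = np.repeat(["a", "b"], 30)
        y = np.where(g == "a", 7.0 - 1e-3 * t, 7.1 - 1.4e-3 * t) + rng.normal(0, 0.01, 60)
        df = pd.DataFrame({"time": t, "ph": y, "group": g})
        res = ancova_slopes(df)
        # two-group slope-difference t-test on the same linear model
        import statsmodels.formula.api as smf

        fit = smf.ols("ph ~ time * C(group)", data=df).fit()
        tval = fit.tvalues["time:C(group)[T.b]"]
        assert res.f_statistic == pytest.approx(tval**2, rel=1e-8)

    def test_null_interaction_p_is_uniform(self):
        # identical slopes: type-I error at 0.05 within binomial CI over 200 reps
        rng = np.random.default_rng(6)
        t = np.tile(np.arange(25, dtype=float), 2)
        g = np.repeat(["a", "b"], 25)
        rejections = 0
        pvals = []
        for _ in range(200):
            y = 7.0 - 1e-3 * t + rng.normal(0, 0.02, 50)
            res = ancova_slopes(pd.DataFrame({"time": t, "ph": y, "group": g}))
            pvals.append(res.p_value)
            rejections += res.p_value < 0.05
        lo, hi = sps.binom.interval(0.99, 200, 0.05)
        assert lo <= rejections <= hi
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_distinct_slopes_detected(self):
        rng = np.random.default_rng(7)
        t = np.tile(np.arange(0, 700, 5, dtype=float), 2)
        g = np.repeat(["nMEC", "Met1"], len(t) // 2)
        y = np.where(g == "nMEC", 7.0 - 0.617e-4 * t, 7.2 - 2.037e-4 * t)
        y = y + rng.normal(0, 0.005, len(t))
        res = ancova_slopes(pd.DataFrame({"time": t, "ph": y, "group": g}))
        assert res.p_value < 0.001
        assert res.slopes["nMEC"] == pytest.approx(-0.617e-4, abs=1e-5)
        assert res.slopes["Met1"] == pytest.approx(-2.037e-4, abs=1e-5)

    def test_per_group_slopes_equal_independent_ols(self):
        rng = np.random.default_rng(8)
        rows = []
        for g, slope in [("a", -1e-4), ("b", -3e-4), ("c", 1e-4)]:
            t = np.arange(0, 400, 5, dtype=float)
            rows.append(pd.DataFrame({"time": t, "ph": 7 + slope * t + rng.normal(0, 0.01, len(t)), "group": g}))
        df = pd.concat(rows, ignore_index=True)
        res = ancova_slopes(df)
        for g, sub in df.groupby("group"):
            assert res.slopes[g] == pytest.approx(sps.linregress(sub.time, sub.ph).slope, rel=1e-12)

    def test_singular_group_named(self):
        df = pd.DataFrame(
            {"time": [0.0] * 6 + [0, 1, 2, 3, 4, 5], "ph": np.arange(12.0), "group": ["bad"] * 6 + ["ok"] * 6}
        )
        with pytest.raises(ValueError, match="bad"):
            ancova_slopes(df)


class TestAnovaSnk:
    def test_family_wise_error_under_global_null(self):
        rng = np.random.default_rng(12)
        fw_errors = 0
        for _ in range(200):
            groups = {g: rng.normal(7.0, 0.05, 12) for g in "abcd"}
            res = anova_snk(groups)
            fw_errors += bool(res.table["significant"].any())
        lo, hi = sps.binom.interval(0.99, 200, 0.05)
        assert fw_errors <= hi  # SNK controls FWE at alpha under the complete null

    def test_figure5_style_pattern(self):
        # Met1 and MINO-high vs nMEC and MINO-low: the alkaline pair separates
        # from the acidic pair; within-pair comparisons are not significant.
        rng = np.random.default_rng(13)
        groups = {
            "Met1": rng.normal(7.18, 0.08, 145),
            "nMEC": rng.normal(6.90, 0.06, 120),
            "MINO_high": rng.normal(7.21, 0.04, 9),
            "MINO_low": rng.normal(6.97, 0.05, 59),
        }
        res = anova_snk(groups)
        sig = {
            tuple(sorted((r.group_a, r.group_b))): r.significant
            for r in res.table.itertuples()
        }
        assert sig[("Met1", "nMEC")] and sig[("MINO_high", "MINO_low")]
        assert sig[("MINO_low", "Met1")] and sig[("MINO_high", "nMEC")]
        assert not sig[("MINO_high", "Met1")]

    def test_identical_constant_groups_not_significant(self):
        rng = np.random.default_rng(14)
        base = rng.normal(7.0, 0.02, 10)
        groups = {"a": base, "b": base.copy(), "c": base + 0.5}
        res = anova_snk(groups)
        row = res.table[(res.table.group_a == "a") & (res.table.group_b == "b")]
        assert not bool(row.significant.iloc[0])

    def test_needs_three_groups_and_n2(self):
        with pytest.raises(ValueError):
            anova_snk({"a": [1, 2], "b": [3, 4]})
        with pytest.raises(ValueError):
            anova_snk({"a": [1, 2], "b": [3, 4], "c": [5]})
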