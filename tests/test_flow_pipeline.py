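"""Gating, thresholding and slope-fitting contracts of the flow pipeline."""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splitfp.flow import (
    CHANNELS,
    ConfigurationError,
    FlowEventTable,
    GatedPopulation,
    LogTable,
    apply_thresholds,
    filter_saturated,
    fit_control_slope,
    fit_split_slope,
    fit_thresholds,
    log_transform,
    run_flow_analysis,
    scatter_gate,
    singlet_gate,
)
from splitfp.scenarios import limit_scenario_config, predicted_slope_for_scenario
from splitfp.simulate.flow import (
    simulate_flow_experiment,
    simulate_full_length_control,
    simulate_untransfected,
)

CEIL = 262143.0


def make_table(n=200, seed=0, ceiling=CEIL) -> FlowEventTable:
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "fsc_a": 10 ** rng.normal(4.7, 0.08, n),
            "ssc_a": 10 ** rng.normal(4.4, 0.12, n),
            "fsc_h": 10 ** rng.normal(4.7, 0.08, n),
            "green": rng.uniform(1, 1000, n),
            "blue": rng.uniform(1, 1000, n),
        }
    )
    return FlowEventTable(df, {ch: ceiling for ch in CHANNELS})


class TestSaturationFilter:
    def test_ceiling_touching_events_removed(self):
        table = make_table(20)
        df = table.events.copy()
        hit = [1, 5, 9, 13]
        for i, ch in zip(hit, ("green", "blue", "fsc_a", "green")):
            df.loc[i, ch] = CEIL
        table = FlowEventTable(df, table.ceilings)
        pop = filter_saturated(table)
        assert pop.counts["saturation"] == 20 - len(hit)
        assert not pop.survivors[hit].any()

    def test_identity_when_all_below(self):
        table = make_table(50)
        pop = filter_saturated(table)
        assert pop.counts["saturation"] == 50

    def test_missing_ceiling_is_configuration_error(self):
        table = make_table(10)
        broken = FlowEventTable(table.events, {"green": CEIL})
        with pytest.raises(ConfigurationError):
            filter_saturated(broken)

    def test_idempotent(self):
        table = make_table(100, seed=3)
        df = table.events.copy()
        df.loc[4, "blue"] = CEIL
        table = FlowEventTable(df, table.ceilings)
        once = filter_saturated(table)
        twice = filter_saturated(once)
        assert np.array_equal(once.survivors, twice.survivors)


class TestScatterGate:
    def test_retain_one_is_identity(self):
        pop = scatter_gate(make_table(500), retain_fraction=1.0)
        assert pop.counts["scatter"] == 500

    def test_retained_fraction_close_to_target(self):
        rng = np.random.default_rng(1)
        n = 10_000
        df = pd.DataFrame(
            {
                "fsc_a": 10 ** rng.normal(4.7, 0.1, n),
                "ssc_a": 10 ** rng.normal(4.4, 0.1, n),
                "fsc_h": np.full(n, 5e4),
                "green": np.full(n, 10.0),
                "blue": np.full(n, 10.0),
            }
        )
        table = FlowEventTable(df, {ch: CEIL for ch in CHANNELS})
        for frac in (0.5, 0.85):
            pop = scatter_gate(table, retain_fraction=frac)
            assert pop.counts["scatter"] / n == pytest.approx(frac, abs=0.02)

    def test_minority_cluster_excluded(self):
        rng = np.random.default_rng(2)
        n_major, n_minor = 9000, 1000
        df = pd.DataFrame(
            {
                "fsc_a": np.concatenate(
                    [10 ** rng.normal(4.7, 0.03, n_major), 10 ** rng.normal(3.0, 0.3, n_minor)]
                ),
                "ssc_a": np.concatenate(
                    [10 ** rng.normal(4.4, 0.03, n_major), 10 ** rng.normal(2.8, 0.3, n_minor)]
                ),
                "fsc_h": np.full(n_major + n_minor, 5e4),
                "green": np.full(n_major + n_minor, 10.0),
                "blue": np.full(n_major + n_minor, 10.0),
            }
        )
        table = FlowEventTable(df, {ch: CEIL for ch in CHANNELS})
        pop = scatter_gate(table, retain_fraction=0.85)
        survivors = pop.survivors
        assert survivors[n_major:].sum() == 0  # debris cluster fully gone

    def test_too_few_events_raises(self):
        with pytest.raises(ValueError):
            scatter_gate(make_table(20), retain_fraction=0.5)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            scatter_gate(make_table(100), retain_fraction=0.0)


class TestSingletGate:
    def test_unity_ratio_retained(self):
        table = make_table(100)
        df = table.events.copy()
        df["fsc_h"] = df["fsc_a"]
        pop = singlet_gate(FlowEventTable(df, table.ceilings))
        assert pop.counts["singlet"] == 100

    def test_wide_band_is_identity(self):
        pop = singlet_gate(make_table(100), band=(1e-9, 1e9))
        assert pop.counts["singlet"] == 100

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            singlet_gate(make_table(100), band=(1.3, 0.8))

    def test_idempotent(self):
        once = singlet_gate(make_table(500, seed=9))
        twice = singlet_gate(once)
        assert np.array_equal(once.survivors, twice.survivors)


class TestLogTransform:
    def test_values(self):
        df = pd.DataFrame(
            {
                "fsc_a": [1.0, 1.0, 1.0],
                "ssc_a": [1.0, 1.0, 1.0],
                "fsc_h": [1.0, 1.0, 1.0],
                "green": [100.0, 1.0, 0.0],
                "blue": [10.0, 1.0, 5.0],
            }
        )
        table = FlowEventTable(df, {ch: CEIL for ch in CHANNELS})
        log = log_transform(table)
        assert log.n_dropped_nonpositive == 1
        np.testing.assert_allclose(log.data["log_green"], [2.0, 0.0])
        np.testing.assert_allclose(log.data["log_blue"], [1.0, 0.0])


class TestThresholds:
    def test_median_quantile_on_known_distribution(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "fsc_a": np.full(20_000, 5e4),
                "ssc_a": np.full(20_000, 2.5e4),
                "fsc_h": np.full(20_000, 5e4),
                "green": 10 ** rng.normal(1.0, 0.2, 20_000),
                "blue": 10 ** rng.normal(0.5, 0.2, 20_000),
            }
        )
        table = FlowEventTable(df, {ch: CEIL for ch in CHANNELS})
        thr = fit_thresholds(log_transform(table), quantile=0.5)
        assert thr["log_green"] == pytest.approx(1.0, abs=0.01)
        assert thr["log_blue"] == pytest.approx(0.5, abs=0.01)

    def test_constant_control(self):
        df = pd.DataFrame(
            {
                "fsc_a": [1.0] * 5, "ssc_a": [1.0] * 5, "fsc_h": [1.0] * 5,
                "green": [10.0] * 5, "blue": [100.0] * 5,
            }
        )
        table = FlowEventTable(df, {ch: CEIL for ch in CHANNELS})
        thr = fit_thresholds(log_transform(table), quantile=0.999)
        assert thr["log_green"] == pytest.approx(1.0)
        assert thr["log_blue"] == pytest.approx(2.0)

    def test_normal_quantile_oracle(self):
        cfg = limit_scenario_config(1.0, seed=4, n_events=100_000)
        cfg = replace(cfg, autofluor_green_mean=20.0, autofluor_green_sd=4.0,
                      autofluor_blue_mean=20.0, autofluor_blue_sd=4.0)
        table = simulate_untransfected(cfg)
        thr = fit_thresholds(log_transform(table), quantile=0.999)
        expected = np.log10(stats.norm.ppf(0.999, 20.0, 4.0))
        assert thr["log_green"] == pytest.approx(expected, abs=0.02)

    def test_empty_control_rejected(self):
        empty = LogTable(pd.DataFrame({"log_green": [], "log_blue": []}), 0)
        with pytest.raises(ValueError):
            fit_thresholds(empty)


class TestSlopeFits:
    def _logtable(self, x, y):
        return LogTable(pd.DataFrame({"log_blue": x, "log_green": y}), 0)

    def test_noiseless_proportional_slope_one(self):
        x = np.linspace(0, 3, 200)
        fit = fit_control_slope(self._logtable(x, x + 0.3))
        assert fit.raw_slope == pytest.approx(1.0, abs=1e-12)
        assert fit.reliable

    def test_green_scaling_shifts_intercept_only(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 3, 500)
        y = x + rng.normal(0, 0.05, 500)
        f1 = fit_control_slope(self._logtable(x, y))
        f2 = fit_control_slope(self._logtable(x, y + np.log10(7.0)))
        assert f2.raw_slope == pytest.approx(f1.raw_slope, abs=1e-12)
        assert f2.raw_intercept - f1.raw_intercept == pytest.approx(np.log10(7.0), abs=1e-12)

    def test_rescaling_divides_by_control(self):
        x = np.linspace(0, 3, 300)
        control = fit_control_slope(self._logtable(x, 0.9 * x))
        split = fit_split_slope(self._logtable(x, 1.35 * x), control)
        assert split.rescaled_slope == pytest.approx(1.5, abs=1e-9)

    def test_nonpositive_control_slope_rejected(self):
        x = np.linspace(0, 3, 300)
        control = fit_control_slope(self._logtable(x, -0.2 * x))
        with pytest.raises(ValueError):
            fit_split_slope(self._logtable(x, x), control)

    def test_small_fit_flagged_unreliable(self):
        x = np.linspace(0, 3, 30)
        fit = fit_control_slope(self._logtable(x, x))
        assert not fit.reliable

    def test_out_of_model_slope_warns(self):
        x = np.linspace(0, 3, 300)
        control = fit_control_slope(self._logtable(x, x))
        with pytest.warns(UserWarning, match="outside the equilibrium-model"):
            fit_split_slope(self._logtable(x, 3.0 * x), control)


class TestPipelineProperties:
    def test_gate_nesting_and_monotone_counts(self, quiet_flow_config):
        table, _ = simulate_flow_experiment(replace(quiet_flow_config, doublet_fraction=0.1))
        pop = singlet_gate(scatter_gate(filter_saturated(table)))
        counts = list(pop.counts.values())
        assert counts == sorted(counts, reverse=True)
        masks = list(pop.masks.values())
        for prev, nxt in zip(masks, masks[1:]):
            assert not np.any(nxt & ~prev)

    def test_scale_equivariance_of_rescaled_slope(self, quiet_flow_config):
        # a unit change of a recorded channel (constant multiplier applied
        # to the stored values and its ceiling alike) must not move the
        # rescaled slope
        cfg = replace(quiet_flow_config, n_events=6000)
        split, _ = simulate_flow_experiment(cfg)
        control = simulate_full_length_control(replace(cfg, seed=101))
        untrans = simulate_untransfected(replace(cfg, seed=102))

        def rescale_channel(table, channel, c):
            df = table.events.copy()
            df[channel] = df[channel] * c
            ceilings = dict(table.ceilings)
            ceilings[channel] = ceilings[channel] * c
            return FlowEventTable(df, ceilings)

        def run(tables):
            report = run_flow_analysis(
                dict(zip(("s", "c", "u"), tables)),
                untransfected="u", full_length="c",
            )
            return report["samples"]["s"]["fit"]["rescaled_slope"]

        base = run((split, control, untrans))
        for channel, c in (("green", 37.0), ("blue", 0.04)):
            scaled = tuple(rescale_channel(t, channel, c) for t in (split, control, untrans))
            assert run(scaled) == pytest.approx(base, abs=1e-9)

    def test_stage_order_matters_on_doublet_rich_data(self, quiet_flow_config):
        cfg = replace(quiet_flow_config, doublet_fraction=0.3, n_events=6000)
        table, _ = simulate_flow_experiment(cfg)
        a = singlet_gate(scatter_gate(filter_saturated(table)))
        b = scatter_gate(singlet_gate(filter_saturated(table)))
        # the KDE density (and so the retained set) depends on what the
        # singlet gate removed first
        assert list(a.masks) == ["saturation", "scatter", "singlet"]
        assert list(b.masks) == ["saturation", "singlet", "scatter"]
        assert a.counts["singlet"] != b.counts["scatter"]

    def test_missing_control_fails_before_fitting(self, quiet_flow_config):
        table, _ = simulate_flow_experiment(quiet_flow_config)
        with pytest.raises(ValueError, match="untransfected"):
            run_flow_analysis({"s": table}, untransfected="u", full_length="c")

    def test_slope_recovery_single_mid_kd(self):
        cfg = limit_scenario_config(1.0, seed=6)
        split, _ = simulate_flow_experiment(cfg)
        control = simulate_full_length_control(replace(cfg, seed=106))
        untrans = simulate_untransfected(replace(cfg, seed=107))
        report = run_flow_analysis(
            {"s": split, "c": control, "u": untrans},
            untransfected="u", full_length="c",
        )
        measured = report["samples"]["s"]["fit"]["rescaled_slope"]
        predicted = predicted_slope_for_scenario(1.0)
        assert measured == pytest.approx(predicted, abs=0.05)
        assert 1.0 < measured < 2.0
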