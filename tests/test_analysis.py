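"""Trace building, blink flagging, EWMA, normalisation, PIPR and aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chromapupil as cp
from chromapupil.analysis import ProcessedTrial
from chromapupil.errors import AnalysisError, ConfigurationError, InputError

TIMING = cp.ProtocolTiming()  # 10/5/25 s at 30 fps


def detections_frame(areas, valid=None, frame_rate=30.0):
    n = len(areas)
    valid = [True] * n if valid is None else valid
    return pd.DataFrame(
        {
            "frame_index": np.arange(n),
            "time_s": np.arange(n) / frame_rate,
            "area_px2": np.asarray(areas, dtype=float),
            "valid": valid,
        }
    )


def constant_trace(area=500.0, n=1200, timing=TIMING):
    return cp.build_trace(detections_frame([area] * n), timing)


class TestBuildTrace:
    def test_last_time_from_frame_index(self):
        trace = constant_trace(n=1200)
        assert trace.times_s[-1] == pytest.approx(39.9667, abs=5e-5)

    def test_all_valid_rows_give_all_valid_trace(self):
        trace = constant_trace()
        assert trace.valid.all()

    def test_duplicate_frame_indices_rejected(self):
        df = detections_frame([1.0, 2.0, 3.0])
        df.loc[2, "frame_index"] = 1
        with pytest.raises(InputError):
            cp.build_trace(df, TIMING)

    def test_simulator_round_trip_preserves_areas(self):
        sim = cp.simulate_trace(cp.blue_preset(), TIMING, noise_sd_pct=1.0, seed=4)
        df = detections_frame(sim.area_px2)
        trace = cp.build_trace(df, TIMING)
        np.testing.assert_array_equal(trace.areas_px2, sim.area_px2)
        np.testing.assert_allclose(trace.times_s, sim.times_s, atol=1e-12)


class TestFlagBlinks:
    def test_constant_trace_gains_no_invalidations(self):
        trace = constant_trace()
        assert cp.flag_blinks(trace).all()

    def test_single_drop_frame_is_invalidated(self):
        areas = [500.0] * 10
        areas[5] = 200.0  # 60% drop, then back
        timing = cp.ProtocolTiming(4.0, 2.0, 4.0, frame_rate=1.0)
        trace = cp.build_trace(detections_frame(areas), timing)
        valid = cp.flag_blinks(trace, max_rel_step=0.5, min_gap_frames=1)
        expected = np.ones(10, dtype=bool)
        expected[5] = False
        np.testing.assert_array_equal(valid, expected)

    def test_short_valid_islands_between_blinks_are_merged(self):
        valid_in = [True] * 4 + [False, False] + [True] + [False, False] + [True] * 4
        areas = [500.0] * len(valid_in)
        timing = cp.ProtocolTiming(5.0, 2.0, 6.0, frame_rate=1.0)
        trace = cp.build_trace(detections_frame(areas, valid=valid_in), timing)
        valid = cp.flag_blinks(trace, min_gap_frames=3)
        assert not valid[4:9].any()  # the lone frame inside the blink is merged
        assert valid[:4].all() and valid[9:].all()

    def test_simulated_blinks_mostly_invalidated(self, rendered_trial,
                                                 rendered_detections, small_timing):
        trace = cp.build_trace(rendered_detections, small_timing)
        valid = cp.flag_blinks(trace)
        blink = ~rendered_trial.valid
        assert (~valid[blink]).mean() >= 0.9


class TestEwmaFilter:
    def test_alpha_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_array_equal(cp.ewma_filter(x, alpha=1.0), x)

    def test_constant_input_is_fixed_point(self):
        x = np.full(20, 7.25)
        np.testing.assert_allclose(cp.ewma_filter(x, alpha=0.3), x)

    def test_unit_step_recursion_by_hand(self):
        x = np.array([0.0, 1.0, 1.0, 1.0])
        np.testing.assert_allclose(
            cp.ewma_filter(x, alpha=0.5), [0.0, 0.5, 0.75, 0.875]
        )

    def test_recursion_skips_invalid_samples(self):
        x = np.array([1.0, 100.0, 1.0])
        valid = np.array([True, False, True])
        y = cp.ewma_filter(x, alpha=0.5, valid=valid)
        assert y[0] == 1.0
        assert np.isnan(y[1])
        assert y[2] == 1.0  # gap did not perturb the recursion

    def test_alpha_out_of_range_rejected(self):
        for alpha in (0.0, -0.5, 1.5):
            with pytest.raises(ConfigurationError):
                cp.ewma_filter(np.ones(3), alpha=alpha)


class TestComputeBaseline:
    def test_constant_areas(self):
        assert cp.compute_baseline(constant_trace(500.0)) == 500.0

    def test_mean_of_valid_values_only(self):
        areas = [500.0, 510.0, 50.0] + [500.0] * 1197
        valid = [True, True, False] + [True] * 1197
        trace = cp.build_trace(detections_frame(areas, valid=valid), TIMING)
        window = trace.times_s < 10.0
        sel = window & trace.valid
        assert cp.compute_baseline(trace) == pytest.approx(
            trace.areas_px2[sel].mean()
        )
        # the hand-computable sub-case: baseline window holds {500, 510, invalid 50}
        short_timing = cp.ProtocolTiming(2.5, 0.5, 1.0, frame_rate=1.0)
        two = cp.build_trace(
            detections_frame(
                [500.0, 510.0, 50.0, 600.0, 600.0], valid=[True, True, False, True, True]
            ),
            short_timing,
        )
        assert cp.compute_baseline(two) == 505.0

    def test_no_valid_baseline_samples_is_analysis_error(self):
        areas = [500.0] * 1200
        valid = [False] * 400 + [True] * 800  # baseline is frames 0..299
        trace = cp.build_trace(detections_frame(areas, valid=valid), TIMING)
        with pytest.raises(AnalysisError):
            cp.compute_baseline(trace)

    def test_recovers_simulated_baseline_within_clt_bound(self):
        noise = 1.0
        sim = cp.simulate_trace(cp.red_preset(), TIMING, noise_sd_pct=noise, seed=9)
        trace = cp.build_trace(detections_frame(sim.area_px2), TIMING)
        base = cp.compute_baseline(trace)
        n = (trace.times_s < 10.0).sum()
        se = sim.kinetics.baseline_area_px2 * (noise / 100.0) / math.sqrt(n)
        assert abs(base - sim.kinetics.baseline_area_px2) < 3 * se


class TestNormalize:
    def test_direct_substitutions(self):
        timing = cp.ProtocolTiming(1.0, 1.0, 1.0, frame_rate=1.0)
        trace = cp.build_trace(detections_frame([40.0, 50.0, 0.0]), timing)
        nt = cp.normalize(trace, baseline_px2=50.0)
        np.testing.assert_allclose(nt.normalized_pct, [80.0, 100.0, 0.0])

    def test_nonpositive_baseline_is_analysis_error(self):
        trace = constant_trace()
        for bad in (0.0, -10.0):
            with pytest.raises(AnalysisError):
                cp.normalize(trace, bad)

    @given(
        baseline=st.floats(1.0, 1e6),
        ratio=st.floats(0.0, 2.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_equation_equals_area_ratio(self, baseline, ratio):
        absolute = baseline * ratio
        implemented = 100.0 - (baseline - absolute) / baseline * 100.0
        assert implemented == pytest.approx(100.0 * absolute / baseline, rel=1e-9,
                                            abs=1e-9)

    def test_baseline_window_mean_is_100(self):
        sim = cp.simulate_trace(cp.blue_preset(), TIMING, noise_sd_pct=1.0, seed=2)
        trace = cp.build_trace(detections_frame(sim.area_px2), TIMING)
        base = cp.compute_baseline(trace)
        nt = cp.normalize(trace, base)
        window = (nt.times_s < TIMING.onset_s) & nt.valid
        assert nt.normalized_pct[window].mean() == pytest.approx(100.0, abs=1e-9)


class TestPiprAt:
    def test_constant_100_trace(self):
        trace = constant_trace(500.0)
        nt = cp.normalize(trace, 500.0)
        assert cp.pipr_at(nt) == pytest.approx(100.0)

    def test_linear_segment_gives_window_center_value(self):
        # normalized curve linear in t: window mean = value at the center
        areas = 500.0 + 2.0 * np.arange(1200)
        trace = cp.build_trace(detections_frame(areas), TIMING)
        nt = cp.normalize(trace, 500.0)
        center_t = TIMING.offset_s + 6.0
        # window is symmetric around a sample (21 s = frame 630 exactly)
        expected = 100.0 * (500.0 + 2.0 * 630) / 500.0
        assert cp.pipr_at(nt, 6.0, 0.25) == pytest.approx(expected, rel=1e-12)
        assert center_t == pytest.approx(630 / 30.0)

    def test_noise_free_blue_preset_matches_ground_truth(self):
        sim = cp.simulate_trace(cp.blue_preset(), TIMING, noise_sd_pct=0.0)
        trace = cp.build_trace(detections_frame(sim.area_px2), TIMING)
        nt = cp.normalize(trace, cp.compute_baseline(trace))
        got = cp.pipr_at(nt, 6.0, 0.25)
        want = cp.ground_truth_pipr(cp.blue_preset(), TIMING)
        assert got == pytest.approx(want, abs=0.5)

    def test_empty_window_is_analysis_error(self):
        trace = constant_trace(500.0)
        with pytest.raises(AnalysisError):
            cp.pipr_at(cp.normalize(trace, 500.0), delay_s=100.0)


class TestPiprDifference:
    def test_red_equals_blue_gives_zero(self):
        assert cp.pipr_difference(90.0, 90.0) == 0.0

    def test_sign_convention_is_red_minus_blue(self):
        assert cp.pipr_difference(97.0, 88.0) == pytest.approx(9.0)
        assert cp.pipr_difference(88.0, 97.0) == pytest.approx(-9.0)


class TestAggregate:
    def _norm(self, areas, baseline):
        trace = cp.build_trace(detections_frame(areas), TIMING)
        return cp.normalize(trace, baseline)

    def test_identical_traces_mean_equals_trace_sd_zero(self):
        nt = self._norm([500.0] * 1200, 500.0)
        grid = np.linspace(0, 39, 100)
        mean, sd = cp.aggregate([nt, nt, nt], grid)
        np.testing.assert_allclose(mean, 100.0)
        np.testing.assert_allclose(sd, 0.0)

    def test_two_constant_traces_sample_sd(self):
        a = self._norm([450.0] * 1200, 500.0)  # 90 %
        b = self._norm([550.0] * 1200, 500.0)  # 110 %
        grid = np.linspace(0, 39, 50)
        mean, sd = cp.aggregate([a, b], grid)
        np.testing.assert_allclose(mean, 100.0)
        np.testing.assert_allclose(sd, math.sqrt(200.0), rtol=1e-12)  # ~14.142

    def test_empty_input_is_analysis_error(self):
        with pytest.raises(AnalysisError):
            cp.aggregate([], np.linspace(0, 39, 10))
        with pytest.raises(AnalysisError):
            cp.aggregate_pipr([])

    def test_normalize_aggregate_order_invariance(self):
        # with a shared baseline, aggregating then normalising equals
        # normalising then aggregating (both are linear maps)
        rng = np.random.default_rng(0)
        baseline = 500.0
        all_areas = [baseline + rng.normal(0, 5, 1200) for _ in range(3)]
        grid = np.linspace(0, 39, 77)
        norm_then_agg, _ = cp.aggregate(
            [self._norm(a, baseline) for a in all_areas], grid
        )
        mean_area = np.mean(all_areas, axis=0)
        agg_then_norm = np.interp(
            grid, np.arange(1200) / 30.0, 100.0 * mean_area / baseline
        )
        np.testing.assert_allclose(norm_then_agg, agg_then_norm, rtol=1e-12)

    def test_three_trials_recover_ground_truth_within_clt(self):
        piprs = []
        want = cp.ground_truth_pipr(cp.blue_preset(), TIMING)
        for seed in range(3):
            sim = cp.simulate_trace(cp.blue_preset(), TIMING, noise_sd_pct=1.0,
                                    seed=seed)
            trace = cp.build_trace(detections_frame(sim.area_px2), TIMING)
            nt = cp.normalize(trace, cp.compute_baseline(trace))
            piprs.append(cp.pipr_at(nt, 6.0, 0.25))
        mean, sd = cp.aggregate_pipr(piprs)
        # window of 16 frames at 1% noise -> se ~ 0.25 per trial
        se = 1.0 / math.sqrt(16) / math.sqrt(3)
        assert abs(mean - want) < 3 * se + 0.05  # + window-averaging bias


class TestProcessTrace:
    def test_full_chain_on_simulated_trace(self):
        sim = cp.simulate_trace(cp.blue_preset(), TIMING, noise_sd_pct=1.0, seed=5)
        trace = cp.build_trace(detections_frame(sim.area_px2), TIMING)
        result = cp.process_trace(trace)
        assert isinstance(result, ProcessedTrial)
        want = cp.ground_truth_pipr(cp.blue_preset(), TIMING)
        assert result.pipr == pytest.approx(want, abs=1.5)
        assert result.valid_fraction > 0.95

    def test_recovered_pipr_decreases_with_sustained_amplitude(self):
        recovered = []
        for a_s in (0.0, 6.0, 12.0):
            k = cp.blue_preset(sustained_amplitude=a_s)
            sim = cp.simulate_trace(k, TIMING, noise_sd_pct=0.2, seed=8)
            trace = cp.build_trace(detections_frame(sim.area_px2), TIMING)
            recovered.append(cp.process_trace(trace).pipr)
        assert recovered[0] > recovered[1] > recovered[2]

    def test_pipr_on_raw_vs_smoothed_are_both_available(self):
        sim = cp.simulate_trace(cp.blue_preset(), TIMING, noise_sd_pct=1.0, seed=6)
        trace = cp.build_trace(detections_frame(sim.area_px2), TIMING)
        smoothed = cp.process_trace(trace, cp.AnalysisConfig(pipr_on_smoothed=True))
        raw = cp.process_trace(trace, cp.AnalysisConfig(pipr_on_smoothed=False))
        want = cp.ground_truth_pipr(cp.blue_preset(), TIMING)
        assert smoothed.pipr == pytest.approx(want, abs=1.5)
        assert raw.pipr == pytest.approx(want, abs=1.5)
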