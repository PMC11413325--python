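"""Preprocessing chain: imputation, alignment, stationarity gate, reframing."""

import numpy as np
import pandas as pd
import pytest

from cgmbench.preprocess import (align_activity, determine_d, impute_series,
                                 reframe, reframe_test, trim_boundaries,
                                 zero_fill_events)


def series_with_mask(values, observed, freq="5min"):
    idx = pd.date_range("2024-01-01", periods=len(values), freq=freq)
    s = pd.Series(np.asarray(values, dtype=float), index=idx)
    m = pd.Series(np.asarray(observed, dtype=bool), index=idx)
    return s, m


class TestImputation:
    def test_train_mode_interpolates_linearly(self):
        s, m = series_with_mask([100, -1, 120], [True, False, True])
        filled, flags = impute_series(s, m, "train")
        assert filled.iloc[1] == pytest.approx(110.0)
        assert list(flags) == [False, True, False]

    def test_test_mode_extrapolates_forward(self):
        s, m = series_with_mask([100, 110, -1, -1],
                                [True, True, False, False])
        filled, _ = impute_series(s, m, "test")
        assert filled.iloc[2] == pytest.approx(120.0)
        assert filled.iloc[3] == pytest.approx(130.0)

    def test_no_gaps_is_identity(self):
        s, m = series_with_mask([100, 105, 99], [True] * 3)
        filled, flags = impute_series(s, m, "test")
        assert filled.equals(s)
        assert not flags.any()

    def test_idempotent_and_preserves_observed(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(120, 20, 60)
        obs = rng.random(60) > 0.3
        obs[[0, 1, -1]] = True
        s, m = series_with_mask(vals, obs)
        once, flags = impute_series(s, m, "train")
        twice, _ = impute_series(once, pd.Series(True, index=s.index),
                                 "train")
        assert twice.equals(once)
        assert np.array_equal(once.to_numpy()[obs], vals[obs])

    def test_test_mode_is_causal(self):
        # changing values after a gap never changes the fill
        vals = [100.0, 104.0, -1.0, -1.0, 50.0, 60.0]
        obs = [True, True, False, False, True, True]
        s, m = series_with_mask(vals, obs)
        base, _ = impute_series(s, m, "test")
        perturbed = s.copy()
        perturbed.iloc[4:] += 500.0
        alt, _ = impute_series(perturbed, m, "test")
        assert np.array_equal(base.to_numpy()[:4], alt.to_numpy()[:4])

    def test_too_few_observed_points_rejected(self):
        s, m = series_with_mask([100, 0, 0], [True, False, False])
        with pytest.raises(ValueError):
            impute_series(s, m, "train")


class TestZeroFill:
    def test_no_events_gives_all_zeros(self):
        grid = pd.date_range("2024-01-01", periods=10, freq="5min")
        out = zero_fill_events(pd.DataFrame({"ts": [], "value": []}), grid)
        assert (out == 0).all()

    def test_event_binned_to_nearest_grid_point(self):
        grid = pd.date_range("2024-01-01 12:00", periods=4, freq="5min")
        events = pd.DataFrame({"ts": [pd.Timestamp("2024-01-01 12:03")],
                               "value": [45.0]})
        out = zero_fill_events(events, grid)
        assert out[pd.Timestamp("2024-01-01 12:05")] == 45.0
        assert out.sum() == 45.0

    def test_simultaneous_events_sum(self):
        grid = pd.date_range("2024-01-01 12:00", periods=3, freq="5min")
        events = pd.DataFrame({
            "ts": [pd.Timestamp("2024-01-01 12:04"),
                   pd.Timestamp("2024-01-01 12:06")],
            "value": [2.0, 3.0]})
        out = zero_fill_events(events, grid)
        assert out[pd.Timestamp("2024-01-01 12:05")] == 5.0


class TestAlignActivity:
    def test_one_minute_series_downsampled_to_nearest(self):
        act_idx = pd.date_range("2024-01-01 00:00", periods=10, freq="1min")
        act = pd.Series(np.arange(10, dtype=float), index=act_idx)
        grid = pd.date_range("2024-01-01 00:00", periods=2, freq="5min")
        out = align_activity(act, grid)
        assert list(out) == [0.0, 5.0]

    def test_aligned_series_unchanged(self):
        grid = pd.date_range("2024-01-01", periods=6, freq="5min")
        act = pd.Series(np.arange(6, dtype=float), index=grid)
        assert align_activity(act, grid).equals(act.rename("activity"))

    def test_tie_chooses_earlier_sample(self):
        act_idx = pd.to_datetime(["2024-01-01 00:04", "2024-01-01 00:06"])
        act = pd.Series([1.0, 2.0], index=act_idx)
        grid = pd.DatetimeIndex([pd.Timestamp("2024-01-01 00:05")])
        assert align_activity(act, grid).iloc[0] == 1.0

    def test_disjoint_spans_rejected(self):
        act = pd.Series([1.0], index=pd.to_datetime(["2023-01-01"]))
        grid = pd.date_range("2024-01-01", periods=3, freq="5min")
        with pytest.raises(ValueError):
            align_activity(act, grid)


class TestTrim:
    def test_identical_spans_unchanged(self):
        grid = pd.date_range("2024-01-01", periods=5, freq="5min")
        chans = {"a": pd.Series(1.0, index=grid),
                 "b": pd.Series(2.0, index=grid)}
        out = trim_boundaries(chans)
        assert out["a"].equals(chans["a"]) and out["b"].equals(chans["b"])

    def test_hour_offset_drops_twelve_points(self):
        g = pd.Series(1.0, index=pd.date_range("2024-01-01 00:00",
                                               periods=60, freq="5min"))
        a = pd.Series(2.0, index=pd.date_range("2024-01-01 01:00",
                                               periods=48, freq="5min"))
        out = trim_boundaries({"glucose": g, "activity": a})
        assert len(out["glucose"]) == len(g) - 12

    def test_nested_spans_reduce_to_innermost(self):
        mk = lambda start, n: pd.Series(
            0.0, index=pd.date_range(start, periods=n, freq="5min"))
        out = trim_boundaries({"a": mk("2024-01-01 00:00", 100),
                               "b": mk("2024-01-01 00:30", 80),
                               "c": mk("2024-01-01 01:00", 40)})
        inner = out["c"].index
        for s in out.values():
            assert s.index.equals(inner)

    def test_empty_intersection_rejected(self):
        a = pd.Series(0.0, index=pd.date_range("2024-01-01", periods=3,
                                               freq="5min"))
        b = pd.Series(0.0, index=pd.date_range("2024-02-01", periods=3,
                                               freq="5min"))
        with pytest.raises(ValueError):
            trim_boundaries({"a": a, "b": b})


class TestStationarityGate:
    def test_white_noise_needs_no_differencing(self):
        rng = np.random.default_rng(11)
        v = determine_d(rng.normal(0, 1, 2000))
        assert v.d == 0
        assert v.is_stationary

    def test_random_walk_needs_one_difference(self):
        rng = np.random.default_rng(11)
        v = determine_d(np.cumsum(rng.normal(0, 1, 2000)))
        assert v.d == 1
        assert not v.is_stationary

    def test_cumulative_sum_adds_exactly_one_order(self):
        rng = np.random.default_rng(23)
        x = rng.normal(0, 1, 1500)
        assert determine_d(np.cumsum(x)).d == determine_d(x).d + 1

    def test_order_capped_at_two(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(np.cumsum(np.cumsum(rng.normal(0, 1, 800))))
        assert determine_d(x).d == 2

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            determine_d(np.full(100, 5.0))


class TestReframe:
    @staticmethod
    def channels(n, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.date_range("2024-01-01", periods=n, freq="5min")
        return {name: pd.Series(rng.normal(size=n), index=idx)
                for name in ("glucose", "carb", "bolus", "activity")}

    def test_pair_count_formula(self):
        frame = reframe(self.channels(20), 12, 6, "univariate")
        assert len(frame) == 20 - 12 - 6 + 1

    def test_multivariate_windows_are_L_by_4(self):
        frame = reframe(self.channels(30), 12, 6, "multivariate")
        assert frame.inputs.shape[1:] == (12, 4)
        assert frame.channels == ("glucose", "carb", "bolus", "activity")

    def test_first_target_equals_raw_series_slice(self):
        ch = self.channels(25)
        frame = reframe(ch, 12, 6, "univariate")
        expected = ch["glucose"].to_numpy()[12:18]
        assert np.array_equal(frame.targets[0], expected)

    def test_targets_reconstruct_series_over_covered_span(self):
        ch = self.channels(40)
        L, H = 8, 4
        frame = reframe(ch, L, H, "univariate")
        reconstructed = np.r_[frame.targets[0], frame.targets[1:, -1]]
        assert np.array_equal(reconstructed,
                              ch["glucose"].to_numpy()[L:])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            reframe(self.channels(10), 12, 6, "univariate")

    def test_test_frame_covers_full_test_span(self, prepared):
        train_ch, _, test_ch, test_imp = prepared
        frame = reframe_test(train_ch, test_ch, 12, 6, "univariate",
                             test_imputed=test_imp)
        assert len(frame) == len(test_ch["glucose"])
        assert frame.target_times.equals(test_ch["glucose"].index)
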