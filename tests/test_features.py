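"""Feature engineering: on-board kinetics, gap filling, normalization,
selection, and windowing."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glyforecast.datatypes import EventLog, InvalidArgumentError
from glyforecast.features import (assemble_feature_matrix, build_windows,
                                  candidate_combinations, carbohydrate_on_board,
                                  insulin_on_board, interpolate_gaps,
                                  iob_remaining_fraction, minmax_fit_transform,
                                  select_features, TargetScaler,
                                  CORE_FEATURES, DEFAULT_SELECTED)

from conftest import make_cgm, make_events

T0 = pd.Timestamp("2024-03-01 08:00")


def _bolus(dose, at=T0):
    return make_events([(str(at), "bolus", dose, "U")])


def _meal(grams, at=T0):
    return make_events([(str(at), "meal", grams, "g")])


class TestIob:
    def test_full_dose_at_injection(self):
        assert insulin_on_board(_bolus(5.0), T0) == pytest.approx(5.0)

    def test_zero_after_four_hours(self):
        assert insulin_on_board(_bolus(5.0), T0 + pd.Timedelta(hours=4)) == 0.0
        assert insulin_on_board(_bolus(5.0), T0 + pd.Timedelta(hours=6)) == 0.0

    def test_superposition_of_two_boluses(self):
        ev = make_events([(str(T0), "bolus", 5.0, "U"),
                          (str(T0 + pd.Timedelta(hours=2)), "bolus", 3.0, "U")])
        t = T0 + pd.Timedelta(hours=3)
        expected = 5.0 * iob_remaining_fraction(3.0) + 3.0 * iob_remaining_fraction(1.0)
        assert insulin_on_board(ev, t) == pytest.approx(float(expected))

    def test_negative_dose_rejected(self):
        with pytest.raises(InvalidArgumentError):
            insulin_on_board(_bolus(-1.0), T0)

    @given(st.floats(min_value=0.0, max_value=6.0))
    @settings(deadline=None, max_examples=50)
    def test_remaining_fraction_monotone_and_bounded(self, h):
        f = float(iob_remaining_fraction(h))
        assert 0.0 <= f <= 1.0
        assert f >= float(iob_remaining_fraction(h + 0.1)) - 1e-12


class TestCob:
    @pytest.mark.parametrize("minutes,expected", [
        (10, 50.0),   # still within the 15-min ingestion delay
        (20, 37.5),   # 50 - 2.5 g/min * 5 min
        (35, 0.0),    # fully absorbed at 15 + 50/2.5 min
    ])
    def test_single_meal_profile(self, minutes, expected):
        t = T0 + pd.Timedelta(minutes=minutes)
        assert carbohydrate_on_board(_meal(50.0), t) == pytest.approx(expected)

    def test_additive_over_meals(self):
        ev = make_events([(str(T0), "meal", 50.0, "g"),
                          (str(T0 + pd.Timedelta(minutes=10)), "meal", 30.0, "g")])
        t = T0 + pd.Timedelta(minutes=20)
        assert carbohydrate_on_board(ev, t) == pytest.approx(37.5 + 30.0)

    def test_negative_carbs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            carbohydrate_on_board(_meal(-5.0), T0)

    def test_nonnegative_everywhere(self):
        ev = _meal(20.0)
        for m in range(0, 120, 5):
            assert carbohydrate_on_board(ev, T0 + pd.Timedelta(minutes=m)) >= 0.0


def _matrix(values):
    cgm = make_cgm(values)
    return assemble_feature_matrix(cgm, EventLog.empty())


def _glucose_only(values):
    """A FeatureMatrix with a single glucose column (no constant helpers)."""
    from glyforecast.features import FeatureMatrix
    cgm = make_cgm(values)
    frame = pd.DataFrame({"timestamp": cgm.times, "glucose": cgm.glucose})
    return FeatureMatrix(frame=frame, observed=frame.drop(columns="timestamp").notna())


class TestInterpolation:
    def test_interior_gap_linear_midpoint(self):
        m = interpolate_gaps(_matrix([10.0, np.nan, 20.0]))
        np.testing.assert_allclose(m.frame["glucose"], [10.0, 15.0, 20.0])

    def test_tail_gap_carry_forward(self):
        m = interpolate_gaps(_matrix([10.0, 20.0, np.nan, np.nan]))
        np.testing.assert_allclose(m.frame["glucose"], [10.0, 20.0, 20.0, 20.0])

    def test_tail_gap_slope_mode(self):
        m = interpolate_gaps(_matrix([10.0, 20.0, np.nan, np.nan]),
                             tail_mode="slope")
        np.testing.assert_allclose(m.frame["glucose"], [10.0, 20.0, 30.0, 40.0])

    def test_leading_gap_left_missing(self):
        m = interpolate_gaps(_matrix([np.nan, 10.0, 20.0]))
        assert np.isnan(m.frame["glucose"].iloc[0])

    def test_truncation_does_not_change_filled_prefix(self):
        """No-look-ahead: filling computed on a prefix equals the prefix of
        the filling computed on the full series."""
        vals = [10.0, np.nan, 20.0, np.nan, np.nan, 30.0, np.nan]
        full = interpolate_gaps(_matrix(vals)).frame["glucose"].to_numpy()
        for cut in range(2, len(vals)):
            part = interpolate_gaps(_matrix(vals[:cut])).frame["glucose"].to_numpy()
            # compare only at rows whose fill is final in both (observed or
            # interior in the prefix); tail fills may legitimately differ
            obs = ~np.isnan(np.asarray(vals[:cut]))
            np.testing.assert_allclose(part[obs], full[:cut][obs])


class TestMinMax:
    def test_basic_scaling(self):
        m = _glucose_only([0.0, 5.0, 10.0])
        normed, scaler = minmax_fit_transform(m, slice(0, 3))
        np.testing.assert_allclose(normed.frame["glucose"], [0.0, 0.5, 1.0])

    def test_inverse_round_trip(self):
        m = _glucose_only(list(np.linspace(60, 300, 20)))
        normed, scaler = minmax_fit_transform(m, slice(0, 20))
        x = np.array([61.0, 150.0, 299.5])
        np.testing.assert_allclose(
            scaler.inverse_col("glucose", scaler.transform_col("glucose", x)),
            x, atol=1e-9)

    def test_test_value_beyond_train_range(self):
        m = _glucose_only([0.0, 5.0, 10.0, 12.0])
        normed, _ = minmax_fit_transform(m, slice(0, 3))
        assert normed.frame["glucose"].iloc[3] == pytest.approx(1.2)

    def test_constant_column_rejected_by_name(self):
        m = _glucose_only([5.0, 5.0, 5.0])
        with pytest.raises(InvalidArgumentError, match="glucose"):
            minmax_fit_transform(m, slice(0, 3))


class TestTargetScaler:
    def test_round_trip_and_scale(self):
        s = TargetScaler.fit(np.array([-40.0, 0.0, 60.0]))
        assert s.scale == pytest.approx(100.0)
        np.testing.assert_allclose(s.inverse(s.transform(np.array([-12.0, 33.0]))),
                                   [-12.0, 33.0], atol=1e-9)


class TestSelection:
    def test_single_combination_returned(self):
        assert select_features({("glucose", "iob"): 50.0}) == ("glucose", "iob")

    def test_argmin(self):
        errors = {("a",): 100.0, ("b",): 90.0, ("c",): 95.0}
        assert select_features(errors) == ("b",)

    def test_tie_breaks_fewer_features_then_lexicographic(self):
        errors = {("a", "b"): 90.0, ("c",): 90.0, ("b",): 90.0}
        assert select_features(errors) == ("b",)

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            select_features({})

    def test_combinations_keep_core_and_one_per_group(self):
        cols = list(DEFAULT_SELECTED) + ["sdnn", "scl_mean"]
        combos = candidate_combinations(cols)
        assert len(combos) == 2 * 2  # {ibi_mean, sdnn} x {scr_mean, scl_mean}
        for combo in combos:
            assert set(CORE_FEATURES) <= set(combo)
            assert sum(c in ("ibi_mean", "sdnn") for c in combo) == 1
            assert sum(c in ("scr_mean", "scl_mean") for c in combo) == 1


class TestWindows:
    def _ready(self, n, rng=None):
        vals = 120 + 30 * np.sin(np.arange(n) / 7.0)
        if rng is not None:
            vals = vals + rng.normal(0, 5, n)
        m = interpolate_gaps(_matrix(list(vals)))
        return m

    def test_window_count_closed_form(self):
        m = self._ready(100)
        ws = build_windows(m, columns=CORE_FEATURES, l=12, horizons=(12,))[12]
        assert len(ws) == 100 - 12 + 1 - 12  # 77

    def test_constant_glucose_zero_targets(self):
        m = interpolate_gaps(_matrix([150.0] * 40))
        ws = build_windows(m, columns=("cob", "iob", "time_index"), l=6,
                           horizons=(3,))[3]
        np.testing.assert_allclose(ws.y_delta, 0.0)

    def test_l_longer_than_series_empty(self):
        m = self._ready(10)
        ws = build_windows(m, columns=CORE_FEATURES, l=50, horizons=(3,))[3]
        assert len(ws) == 0

    def test_gap_at_target_drops_window(self):
        vals = [120.0] * 30
        vals[20] = np.nan
        m = interpolate_gaps(_matrix(vals))
        ws = build_windows(m, columns=CORE_FEATURES, l=6, horizons=(3,))[3]
        assert 17 not in ws.t_idx  # its target row 20 is a declared gap
        assert 20 not in ws.t_idx  # anchor itself unobserved

    def test_window_contents_match_matrix_slices(self):
        m = self._ready(60, np.random.default_rng(0))
        ws = build_windows(m, columns=CORE_FEATURES, l=12, horizons=(6,))[6]
        data = m.frame[list(ws.columns)].to_numpy()
        for i in (0, len(ws) // 2, len(ws) - 1):
            t = ws.t_idx[i]
            np.testing.assert_array_equal(ws.X[i], data[t - 11:t + 1])
            assert ws.y_delta[i] == pytest.approx(
                m.frame["glucose"].iloc[t + 6] - m.frame["glucose"].iloc[t])

    def test_invalid_length_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_windows(self._ready(30), l=0)


class TestPipelineCausality:
    def test_prefix_truncation_invariance(self, small_cohort):
        """Dropping all rows after time t never changes any window at <= t."""
        from glyforecast.features import prepare_subject_windows
        sub = small_cohort[0]
        n = len(sub.cgm)
        full, _ = prepare_subject_windows(sub.cgm, sub.events, sub.grid_physio,
                                          horizons=(6,), fit_fraction=0.5)
        cut = n * 3 // 4
        from glyforecast.datatypes import CgmSeries
        cgm_cut = CgmSeries(sub.cgm.times[:cut], sub.cgm.glucose[:cut])
        physio_cut = sub.grid_physio.iloc[:cut]
        # hold the normalization fit rows identical (scaler constants are a
        # training-range property, not part of the causal feature pipeline)
        part, _ = prepare_subject_windows(cgm_cut, sub.events, physio_cut,
                                          horizons=(6,),
                                          fit_fraction=(n * 0.5) / cut)
        fw, pw = full[6], part[6]
        # windows of the truncated run, excluding those near the cut whose
        # tail-fill state differs, must match the full run exactly
        safe = pw.t_idx < cut - 24
        common = np.isin(fw.t_idx, pw.t_idx[safe])
        sel = np.isin(pw.t_idx, fw.t_idx[common]) & safe
        np.testing.assert_allclose(pw.X[sel], fw.X[common], atol=1e-9)
        np.testing.assert_allclose(pw.y_delta[sel], fw.y_delta[common], atol=1e-9)
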