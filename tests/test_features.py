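"""Rolling-window aggregates, interaction terms and the theory-driven catalog."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import userjourney as uj
from userjourney.features import (
    RollingSpec,
    clock_diff_minutes,
    completion_latency,
    days_since_last_contact,
    default_catalog,
    event_indicator,
    parse_clock_minutes,
)
from userjourney.touchpoints import UserFeatureTable


def _log(rows: str) -> uj.TouchPointLog:
    return uj.parse_touchpoints(io.StringIO("user_id,timestamp,variable,value,source\n" + rows))


class TestRolling:
    def test_hand_computed_window_three(self):
        out = uj.rolling_window_features([1, 2, 3, 4, 5], RollingSpec("mood", 3))
        assert out["mood_sum3"].tolist() == [6, 9, 12]
        assert out["mood_mean3"].tolist() == [2, 3, 4]
        assert out["mood_min3"].tolist() == [1, 2, 3]
        assert out["mood_max3"].tolist() == [3, 4, 5]
        assert np.allclose(out["mood_sd3"], [1, 1, 1])

    def test_window_one_is_identity_with_undefined_sd(self):
        s = [3.0, 1.0, 4.0]
        out = uj.rolling_window_features(s, RollingSpec("x", 1))
        for stat in ("sum", "mean", "min", "max"):
            assert out[f"x_{stat}1"].tolist() == s
        assert out["x_sd1"].isna().all()  # sample variance undefined at n=1

    def test_constant_series(self):
        out = uj.rolling_window_features([5, 5, 5], RollingSpec("x", 3))
        assert out["x_sum3"].tolist() == [15]
        assert out["x_sd3"].tolist() == [0]

    def test_window_longer_than_series_yields_no_rows(self):
        out = uj.rolling_window_features([1, 2], RollingSpec("x", 5))
        assert len(out) == 0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            RollingSpec("x", 0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=20), st.integers(1, 6))
    def test_output_length_property(self, xs, w):
        out = uj.rolling_window_features(xs, RollingSpec("x", w))
        assert len(out) == max(0, len(xs) - w + 1)


class TestInteractions:
    def test_elementwise_product(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out = uj.interaction_terms(df, [("a", "b")])
        assert out["a_x_b"].tolist() == [3.0, 8.0]

    def test_zero_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "z": [0.0, 0.0]})
        assert uj.interaction_terms(df, [("a", "z")])["a_x_z"].tolist() == [0.0, 0.0]

    def test_all_pairs_count(self):
        df = pd.DataFrame(np.ones((3, 5)), columns=list("abcde"))
        out = uj.interaction_terms(df, "all")
        assert out.shape[1] == 5 + 5 * 4 // 2

    def test_self_pair_is_square(self):
        df = pd.DataFrame({"a": [2.0, -3.0]})
        assert uj.interaction_terms(df, [("a", "a")])["a_x_a"].tolist() == [4.0, 9.0]

    def test_categorical_member_rejected(self):
        t = UserFeatureTable(pd.DataFrame({"a": [1.0], "c": ["x"]}),
                             {"a": "numeric", "c": "categorical"})
        with pytest.raises(ValueError, match="categorical"):
            uj.interaction_terms(t, [("a", "c")])

    def test_missing_propagates(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [3.0, 4.0]})
        out = uj.interaction_terms(df, [("a", "b")])
        assert np.isnan(out["a_x_b"].iloc[1])


class TestEventAndGapFeatures:
    def test_indicator_one_regardless_of_multiplicity(self):
        log = _log(
            "a,2021-01-03T08:00:00,login,,system\n"
            "a,2021-01-03T18:00:00,login,,system\n"
            "a,2021-01-04T09:00:00,mood,3,self_report\n"
        )
        ind = event_indicator(log, "login")
        assert ind.loc[("a", pd.Timestamp("2021-01-03"))] == 1
        assert ind.loc[("a", pd.Timestamp("2021-01-04"))] == 0

    def test_unknown_event_type_rejected(self, tiny_log):
        with pytest.raises(KeyError):
            event_indicator(tiny_log, "nonexistent")

    def test_days_since_last_contact_enumeration(self):
        # contacts on days 1 and 4 (of an observed day-1..4 span)
        log = _log(
            "a,2021-01-01T08:00:00,login,,system\n"
            "a,2021-01-04T08:00:00,login,,system\n"
        )
        gap = days_since_last_contact(log)
        days = {d.day: v for (_, d), v in gap.items()}
        assert days == {1: 0, 2: 1, 3: 2, 4: 0}

    def test_no_contacts_all_missing(self):
        log = _log("a,2021-01-01T08:00:00,mood,3,self_report\n")
        gap = days_since_last_contact(log, sources=("system",))
        assert gap.isna().all()


class TestCompletionLatency:
    def _core_log(self, pairs):
        rows = ""
        for c, (avail, done) in enumerate(pairs):
            rows += f"a,2021-01-{avail + 1:02d}T12:00:00,core_available_{c},,system\n"
            if done is not None:
                rows += f"a,2021-01-{done + 1:02d}T12:00:00,core_completed_{c},,system\n"
        return _log(rows)

    def test_three_day_core(self):
        lat = completion_latency(self._core_log([(0, 3)]))
        assert lat.loc["a", "core_0_completion_days"] == 3

    def test_running_average(self):
        lat = completion_latency(self._core_log([(0, 3), (10, 15)]))
        assert lat.loc["a", "avg_core_completion_time"] == 4.0  # mean of 3 and 5

    def test_incomplete_core_missing(self):
        lat = completion_latency(self._core_log([(0, 3), (10, None)]))
        assert np.isnan(lat.loc["a", "core_1_completion_days"])

    def test_completion_before_availability_is_error(self):
        with pytest.raises(ValueError, match="before availability"):
            completion_latency(self._core_log([(5, 2)]))

    def test_running_average_equals_mean_of_observed(self, small_cohort):
        log, _, _ = small_cohort
        lat = completion_latency(log)
        cols = [f"core_{c}_completion_days" for c in range(7)]
        expected = lat[cols].mean(axis=1)
        pd.testing.assert_series_equal(
            lat["avg_core_completion_time"], expected, check_names=False
        )


class TestClockArithmetic:
    def test_parse_and_malformed(self):
        vals = parse_clock_minutes(pd.Series(["06:30", "23:59", "7:05", "bogus", "25:00"]))
        assert vals.tolist()[:3] == [390.0, 1439.0, 425.0]
        assert vals.isna().tolist()[3:] == [True, True]

    def test_shortest_signed_interval_across_midnight(self):
        a = pd.Series([23 * 60.0, 6 * 60.0, 390.0])
        b = pd.Series([1 * 60.0, 5 * 60.0, 420.0])
        assert clock_diff_minutes(a, b).tolist() == [120.0, -60.0, 30.0]


class TestCatalog:
    def test_catalog_has_twenty_five_entries(self):
        cat = default_catalog()
        assert len(cat) == 25
        aggs = pd.Series([c.user_agg for c in cat]).value_counts()
        assert aggs["sum"] == 8 and aggs["last"] == 12 and aggs["mean"] == 5
        assert all(c.protected for c in cat)

    def test_awake_to_arise_thirty_minutes(self):
        log = _log(
            "a,2021-01-01T09:00:00,awake_time,06:30,self_report\n"
            "a,2021-01-01T09:00:00,arise_time,07:00,self_report\n"
        )
        base = UserFeatureTable(pd.DataFrame(index=pd.Index(["a"], name="user_id")), {})
        out, _ = uj.apply_feature_catalog(base, log)
        assert out.data.loc["a", "awake_to_arise_minutes"] == 30.0

    def test_eight_hour_sleep_window_flagged(self):
        log = _log(
            "a,2021-01-01T09:00:00,bedtime,23:00,self_report\n"
            "a,2021-01-01T09:00:00,arise_time,07:00,self_report\n"
        )
        base = UserFeatureTable(pd.DataFrame(index=pd.Index(["a"], name="user_id")), {})
        out, _ = uj.apply_feature_catalog(base, log)
        assert out.data.loc["a", "sleep_window_5_or_8h"] == 1.0

    def test_decreasing_sleep_duration_counts_transitions(self):
        rows = ""
        # three one-day cores with mean durations 7.5, 7.0, 6.5
        for c, (day, dur) in enumerate([(1, 7.5), (5, 7.0), (9, 6.5)]):
            rows += f"a,2021-01-{day:02d}T12:00:00,core_available_{c},,system\n"
            rows += f"a,2021-01-{day:02d}T09:00:00,sleep_duration,{dur},self_report\n"
            rows += f"a,2021-01-{day + 1:02d}T12:00:00,core_completed_{c},,system\n"
        log = _log(rows)
        base = UserFeatureTable(pd.DataFrame(index=pd.Index(["a"], name="user_id")), {})
        out, _ = uj.apply_feature_catalog(base, log)
        assert out.data.loc["a", "sleep_duration_decreasing"] == 2.0

    def test_absent_base_variable_gives_missing_column_with_warning(self, caplog):
        log = _log("a,2021-01-01T08:00:00,login,,system\n")
        base = UserFeatureTable(pd.DataFrame(index=pd.Index(["a"], name="user_id")), {})
        with caplog.at_level("WARNING"):
            out, prov = uj.apply_feature_catalog(base, log)
        assert np.isnan(out.data.loc["a", "naptime_minutes"])
        assert "absent" in caplog.text
        assert set(prov) == {c.name for c in default_catalog()}

    def test_catalog_columns_are_protected(self, small_cohort):
        log, labels, _ = small_cohort
        from userjourney.modeling import build_core_table
        from userjourney.experiments import study_config

        uft = build_core_table(log, labels, study_config(7), 2)
        assert {"avg_core_completion_time", "days_since_last_contact",
                "login_day"} <= uft.protected


class TestCatalogFile:
    def test_catalog_round_trips_through_yaml(self, tmp_path):
        from userjourney.features import load_catalog, save_catalog

        cat = default_catalog()
        path = tmp_path / "catalog.yaml"
        save_catalog(cat, path)
        back = load_catalog(path)
        assert [(c.name, c.kind, c.user_agg) for c in back] == \
               [(c.name, c.kind, c.user_agg) for c in cat]
        assert all(c.protected for c in back)
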