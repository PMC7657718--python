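"""Long-format ingestion and the raw-to-wide journey transformation."""

import io

import numpy as np
import pandas as pd
import pytest

import userjourney as uj
from userjourney.touchpoints import (
    JourneyTable,
    VariableSpec,
    core_completion_dates,
    default_spec,
    user_level_aggregate,
)


def _log(rows: str) -> uj.TouchPointLog:
    return uj.parse_touchpoints(io.StringIO("user_id,timestamp,variable,value,source\n" + rows))


class TestParse:
    def test_well_formed_rows_sorted(self, tiny_log):
        assert len(tiny_log) == 6
        ts = tiny_log.data.groupby("user_id")["timestamp"]
        assert (ts.apply(lambda s: s.is_monotonic_increasing)).all()
        assert tiny_log.value_types == {
            "mood": "numeric", "login": "event", "color": "categorical",
        }

    def test_empty_file_with_header(self):
        log = _log("")
        assert len(log) == 0

    def test_mixed_numeric_categorical_is_hard_error(self):
        with pytest.raises(ValueError, match="mood"):
            _log(
                "a,2021-01-01T09:00:00,mood,3,self_report\n"
                "a,2021-01-02T09:00:00,mood,high,self_report\n"
            )

    def test_unparseable_timestamp_rejected_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            log = _log(
                "a,2021-01-01T09:00:00,mood,3,self_report\n"
                "a,not-a-time,mood,4,self_report\n"
            )
        assert len(log) == 1
        assert "unparseable" in caplog.text

    def test_events_carry_implicit_value_one(self, tiny_log):
        logins = tiny_log.data[tiny_log.data["variable"] == "login"]
        assert (logins["numeric_value"] == 1.0).all()

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing required"):
            uj.parse_touchpoints(io.StringIO("user_id,timestamp,value\n"))


class TestAssignWindows:
    def _daily(self, days, w, **kw):
        rows = "".join(f"a,2021-01-{d + 1:02d}T09:00:00,mood,{i},self_report\n"
                       for i, d in enumerate(days))
        return uj.assign_windows(_log(rows), window_days=w, **kw)

    def test_daily_window_indices(self):
        out = self._daily([0, 0, 2], w=1)
        assert out.data["window_index"].tolist() == [0, 0, 2]

    def test_half_open_boundary_day_seven(self):
        out = self._daily([0, 7], w=7)
        assert out.data["window_index"].tolist() == [0, 1]

    def test_three_day_windows_enumeration(self):
        # days 0..8 with w=3 -> 0,0,0,1,1,1,2,2,2
        out = self._daily(range(9), w=3)
        assert out.data["window_index"].tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_window_length_must_be_positive(self, tiny_log):
        with pytest.raises(ValueError):
            uj.assign_windows(tiny_log, window_days=0)

    def test_touchpoint_before_fixed_origin_errors(self, tiny_log):
        with pytest.raises(ValueError, match="before the fixed origin"):
            uj.assign_windows(tiny_log, 1, origin="fixed_date", origin_date="2021-01-02")

    def test_daily_windows_bijective_on_dates(self, small_cohort):
        log, _, _ = small_cohort
        out = uj.assign_windows(log, 1)
        d = out.data
        day = (d["timestamp"].dt.normalize()
               - d.groupby("user_id")["timestamp"].transform("min").dt.normalize()).dt.days
        assert (d["window_index"] == day).all()


class TestAggregate:
    def test_numeric_mean_within_window(self, tiny_log):
        jt = uj.aggregate_within_window(uj.assign_windows(tiny_log, 1))
        assert jt.data.loc[("a", 0), "mood"] == 3.0  # mean of 2 and 4

    def test_event_sum_within_window(self):
        rows = "".join("a,2021-01-01T0%d:00:00,login,,system\n" % h for h in range(1, 4))
        jt = uj.aggregate_within_window(uj.assign_windows(_log(rows), 1))
        assert jt.data.loc[("a", 0), "login"] == 3

    def test_categorical_mode(self):
        rows = (
            "a,2021-01-01T09:00:00,ans,yes,self_report\n"
            "a,2021-01-01T10:00:00,ans,yes,self_report\n"
            "a,2021-01-01T11:00:00,ans,no,self_report\n"
        )
        jt = uj.aggregate_within_window(uj.assign_windows(_log(rows), 1))
        assert jt.data.loc[("a", 0), "ans"] == "yes"

    def test_mode_tie_breaks_to_earliest_observed(self):
        rows = (
            "a,2021-01-01T09:00:00,ans,no,self_report\n"
            "a,2021-01-01T10:00:00,ans,yes,self_report\n"
        )
        jt = uj.aggregate_within_window(uj.assign_windows(_log(rows), 1))
        assert jt.data.loc[("a", 0), "ans"] == "no"

    def test_window_without_touchpoint_is_missing(self, tiny_log):
        jt = uj.aggregate_within_window(uj.assign_windows(tiny_log, 1))
        assert np.isnan(jt.data.loc[("a", 2), "mood"])  # only a login that day

    def test_event_sum_conserves_raw_counts(self, small_cohort):
        log, _, _ = small_cohort
        jt = uj.aggregate_within_window(uj.assign_windows(log, 1))
        raw = int((log.data["variable"] == "login").sum())
        assert jt.data["login"].sum() == raw

    def test_duplicating_touchpoints_doubles_sums_keeps_means(self, tiny_log):
        dup = uj.parse_touchpoints(
            pd.concat([tiny_log.data, tiny_log.data])[
                ["user_id", "timestamp", "variable", "value", "source"]
            ].assign(timestamp=lambda d: d["timestamp"].astype(str))
        )
        jt1 = uj.aggregate_within_window(uj.assign_windows(tiny_log, 1))
        jt2 = uj.aggregate_within_window(uj.assign_windows(dup, 1))
        assert jt2.data["login"].sum() == 2 * jt1.data["login"].sum()
        pd.testing.assert_series_equal(jt1.data["mood"], jt2.data["mood"])
        pd.testing.assert_series_equal(jt1.data["color"], jt2.data["color"])


class TestCarryForward:
    def _jt(self, cells):
        """One user, one numeric questionnaire observed at given windows."""
        rows = "".join(
            f"a,2021-01-{d + 1:02d}T09:00:00,isi,{v},self_report\n" for d, v in cells
        ) + "".join(
            f"a,2021-01-{d:02d}T08:00:00,login,,system\n" for d in range(1, 8)
        )
        specs = {"isi": VariableSpec("isi", "numeric", carry_forward=True)}
        return uj.aggregate_within_window(uj.assign_windows(_log(rows), 1), specs)

    def test_locf_fills_until_next_occurrence(self):
        jt = uj.carry_forward(self._jt([(0, 15), (6, 11)]))
        assert jt.data["isi"].tolist() == [15, 15, 15, 15, 15, 15, 11]

    def test_cells_before_first_observation_stay_missing(self):
        jt = uj.carry_forward(self._jt([(3, 9)]))
        vals = jt.data["isi"].tolist()
        assert all(np.isnan(v) for v in vals[:3]) and vals[3:] == [9, 9, 9, 9]

    def test_all_missing_stays_missing(self):
        jt = self._jt([])
        out = uj.carry_forward(jt, features=["login"])  # no-op on complete col
        assert "isi" not in jt.data.columns or out.data.notna().all().all()

    def test_identity_when_fully_observed(self):
        jt = self._jt([(d, d) for d in range(7)])
        out = uj.carry_forward(jt)
        pd.testing.assert_frame_equal(out.data, jt.data)

    def test_idempotent(self):
        once = uj.carry_forward(self._jt([(0, 15), (6, 11)]))
        twice = uj.carry_forward(once)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestDropConstantCategoricals:
    def test_single_level_removed_two_level_kept(self):
        rows = (
            "a,2021-01-01T09:00:00,flag,no,self_report\n"
            "b,2021-01-01T09:00:00,flag,no,self_report\n"
            "a,2021-01-01T10:00:00,pick,x,self_report\n"
            "b,2021-01-01T10:00:00,pick,y,self_report\n"
        )
        jt = uj.aggregate_within_window(uj.assign_windows(_log(rows), 1))
        out, removed = uj.drop_constant_categoricals(jt)
        assert removed == ["flag"]
        assert "pick" in out.data.columns

    def test_all_missing_categorical_removed(self):
        rows = (
            "a,2021-01-01T09:00:00,pick,x,self_report\n"
            "b,2021-01-02T09:00:00,color,blue,self_report\n"
        )
        jt = uj.aggregate_within_window(uj.assign_windows(_log(rows), 1))
        # 'pick' missing for b's row, 'color' missing for a's: single observed
        # level each -> both removed
        out, removed = uj.drop_constant_categoricals(jt)
        assert set(removed) == {"pick", "color"}


class TestUserLevelAggregate:
    def _table(self):
        rows = ""
        for d, logged in enumerate([1, 0, 1, 1]):
            if logged:
                rows += f"a,2021-01-{d + 1:02d}T08:00:00,login,,system\n"
            rows += f"a,2021-01-{d + 1:02d}T09:00:00,diary,{4 + 2 * (d % 2)},self_report\n"
        specs = {"diary": VariableSpec("diary", "numeric", "mean", "mean")}
        return uj.aggregate_within_window(uj.assign_windows(_log(rows), 1), specs)

    def test_sum_of_daily_login_indicator(self):
        out = user_level_aggregate(self._table())
        assert out.data.loc["a", "login"] == 3

    def test_mean_of_diary(self):
        out = user_level_aggregate(self._table())
        assert out.data.loc["a", "diary"] == 5.0  # mean of 4,6,4,6

    def test_last_takes_last_observation(self):
        rows = (
            "a,2021-01-01T09:00:00,lat,3,self_report\n"
            "a,2021-01-05T09:00:00,lat,5,self_report\n"
        )
        specs = {"lat": VariableSpec("lat", "numeric", "mean", "last")}
        jt = uj.aggregate_within_window(uj.assign_windows(_log(rows), 1), specs)
        out = user_level_aggregate(jt)
        assert out.data.loc["a", "lat"] == 5

    def test_labels_attached_and_validated(self):
        out = user_level_aggregate(self._table(), labels={"a": 1})
        assert out.y.loc["a"] == 1
        with pytest.raises(ValueError, match="labels missing"):
            user_level_aggregate(self._table(), labels={"zz": 1})

    def test_core_cutoff_restricts_users_and_windows(self, small_cohort):
        log, labels, _ = small_cohort
        jt = uj.aggregate_within_window(uj.assign_windows(log, 1))
        completion = core_completion_dates(log)
        n_prev = None
        for c in range(6):
            out = user_level_aggregate(jt, labels=labels, core_cutoff=c,
                                       completion_dates=completion)
            n = len(out.data)
            assert n == completion[c].notna().sum()
            if n_prev is not None:
                assert n <= n_prev  # mirrors the declining per-core N
            n_prev = n

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="mode aggregation"):
            VariableSpec("x", "numeric", "mode", "mean")
        with pytest.raises(ValueError, match="sum aggregation"):
            VariableSpec("x", "categorical", "mode", "sum")
        assert default_spec("e", "event").within_window_agg == "sum"


class TestSpecFile:
    def test_variable_specs_load_from_yaml(self, tmp_path):
        from userjourney.touchpoints import load_variable_specs

        path = tmp_path / "specs.yaml"
        path.write_text(
            "- {name: isi, value_type: numeric, within_window_agg: mean,"
            " user_agg: last, carry_forward: true}\n"
            "- {name: login, value_type: event, within_window_agg: sum,"
            " user_agg: sum}\n"
        )
        specs = load_variable_specs(path)
        assert specs["isi"].carry_forward and specs["isi"].user_agg == "last"
        assert specs["login"].value_type == "event"
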