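import numpy as np  # noqa: F401  (used in fixtures below)
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from foragekit import (
    BanditConfig,
    Cohort,
    FormatError,
    LogValidationError,
    SessionLog,
    WSLSParams,
    read_event_csv,
    read_fed3_native_csv,
    simulate_session,
    split_days,
    validate_log,
    write_event_csv,
)


def _write(tmp_path, text, name="log.csv"):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestReadWrite:
    def test_three_row_csv_transcribed_in_order(self, tmp_path):
        path = _write(
            tmp_path,
            "# mouse_id=m7\n# sex=M\n# task=fr1\n# day_index=2\n"
            "time_s,event,active_side,block_index\n"
            "0.5,poke_left,left,0\n0.7,pellet,left,0\n3.0,retrieval,left,0\n",
        )
        log = read_event_csv(path)
        assert log.mouse_id == "m7" and log.sex == "M"
        assert log.task == "fr1" and log.day_index == 2
        assert list(log.events["event"]) == ["poke_left", "pellet", "retrieval"]
        assert log.events["time_s"].is_monotonic_increasing

    def test_empty_file_with_header_gives_zero_events(self, tmp_path):
        path = _write(tmp_path, "time_s,event,active_side,block_index\n")
        assert read_event_csv(path).n_events == 0

    def test_missing_column_names_the_column(self, tmp_path):
        path = _write(tmp_path, "time_s,event,block_index\n1.0,pellet,0\n")
        with pytest.raises(FormatError, match="active_side"):
            read_event_csv(path)

    def test_non_monotone_timestamps_list_rows(self, tmp_path):
        path = _write(
            tmp_path,
            "time_s,event,active_side,block_index\n"
            "5.0,poke_left,left,0\n2.0,poke_left,left,0\n",
        )
        with pytest.raises(LogValidationError, match=r"\[1\]"):
            read_event_csv(path)

    def test_wall_clock_timestamps_converted_to_relative_seconds(self, tmp_path):
        path = _write(
            tmp_path,
            "time_s,event,active_side,block_index\n"
            "2024-01-01 10:00:00,poke_left,left,0\n"
            "2024-01-01 10:00:30,pellet,left,0\n",
        )
        log = read_event_csv(path)
        assert log.events["time_s"].tolist() == [0.0, 30.0]

    def test_metadata_from_filename_pattern(self, tmp_path):
        path = _write(
            tmp_path,
            "time_s,event,active_side,block_index\n",
            name="f012_bandit_80_20_day2.csv",
        )
        log = read_event_csv(path)
        assert log.mouse_id == "f012"
        assert log.task == "bandit_80_20"
        assert log.day_index == 2

    def test_round_trip_on_simulated_session(self, tmp_path, bandit_session):
        path = str(tmp_path / "rt.csv")
        write_event_csv(bandit_session, path)
        assert read_event_csv(path).equals(bandit_session)

    def test_two_writes_byte_identical(self, tmp_path, bandit_session):
        p1 = write_event_csv(bandit_session, str(tmp_path / "a.csv"))
        p2 = write_event_csv(bandit_session, str(tmp_path / "b.csv"))
        assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_zero_event_log_round_trips(self, tmp_path):
        log = SessionLog("m1", "F", "pr1", 1)
        path = write_event_csv(log, str(tmp_path / "empty.csv"))
        again = read_event_csv(path)
        assert again.n_events == 0 and again.equals(log)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), w=st.floats(0.5, 1.0))
    def test_round_trip_identity_on_random_sessions(self, tmp_path_factory, seed, w):
        log = simulate_session(
            WSLSParams(w=w), BanditConfig(0.8, 0.2), n_trials=40, seed=seed
        )
        path = str(tmp_path_factory.mktemp("rt") / "s.csv")
        write_event_csv(log, path)
        assert read_event_csv(path).equals(log)

    def test_pellet_row_count_conserved(self, tmp_path, bandit_session):
        path = write_event_csv(bandit_session, str(tmp_path / "c.csv"))
        n_pellet_rows = sum(",pellet," in line for line in open(path))
        assert n_pellet_rows == (bandit_session.events["event"] == "pellet").sum()


class TestValidateLog:
    def test_valid_simulated_log_is_clean(self, bandit_session):
        assert validate_log(bandit_session) == []

    def test_retrieval_without_pellet_cites_rule(self):
        ev = pd.DataFrame(
            {
                "time_s": [1.0],
                "event": ["retrieval"],
                "active_side": ["left"],
                "block_index": [0],
            }
        )
        issues = validate_log(SessionLog("m", "F", "fr1", 1, ev))
        assert len(issues) == 1
        assert "pellet-before-retrieval" in issues[0] and "row 0" in issues[0]

    def test_single_out_of_order_timestamp_single_issue(self, tiny_log):
        ev = tiny_log.events.copy()
        ev.loc[1, "time_s"] = 0.5
        issues = validate_log(SessionLog("m", "F", "fr1", 1, ev))
        assert sum("time-order" in i for i in issues) == 1

    def test_pellet_retrieval_conservation_in_simulation(self, bandit_session):
        n_p = (bandit_session.events["event"] == "pellet").sum()
        n_r = (bandit_session.events["event"] == "retrieval").sum()
        assert n_r <= n_p <= n_r + 1

    def test_validation_never_raises_on_garbage(self):
        ev = pd.DataFrame(
            {
                "time_s": [0.0, 1.0],
                "event": ["warp", "poke_left"],
                "active_side": ["up", "left"],
                "block_index": [0, 0],
            }
        )
        issues = validate_log(SessionLog("m", "X", "nap", 0, ev))
        assert any("event-kind" in i for i in issues)
        assert any("active-side" in i for i in issues)
        assert any("task-label" in i for i in issues)


class TestCohortAndSplit:
    def test_duplicate_mouse_task_day_rejected(self, tiny_log):
        with pytest.raises(LogValidationError, match="duplicate"):
            Cohort([tiny_log, tiny_log])

    def test_split_days_rebases_times(self):
        ev = pd.DataFrame(
            {
                "time_s": [10.0, 86400.0 + 5.0],
                "event": ["poke_left", "poke_left"],
                "active_side": ["left", "left"],
                "block_index": [0, 0],
            }
        )
        days = split_days(SessionLog("m", "F", "fr1", 1, ev))
        assert [d.day_index for d in days] == [1, 2]
        assert days[1].events["time_s"].tolist() == [5.0]


class TestNativeAdapter:
    def test_native_fed3_rows_mapped_and_retrievals_expanded(self, tmp_path):
        p = _write(
            tmp_path,
            "MM:DD:YYYY hh:mm:ss,Event,Active_Poke,Block_Pellet_Count,Retrieval_Time\n"
            "01/02/2024 09:00:00,Left,Left,0,\n"
            "01/02/2024 09:00:01,Pellet,Left,1,2.5\n"
            "01/02/2024 09:00:20,Right,Left,1,\n",
        )
        log = read_fed3_native_csv(p, task="bandit_100_0", mouse_id="m9")
        assert list(log.events["event"]) == ["poke_left", "pellet", "retrieval", "poke_right"]
        assert log.events["time_s"].tolist() == [0.0, 1.0, 3.5, 20.0]
        assert validate_log(log) == []
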