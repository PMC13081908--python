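import numpy as np
import pandas as pd
import pytest

from foragekit import (
    BanditConfig,
    Cohort,
    SessionLog,
    WSLSParams,
    apply_exclusions,
    binned_accuracy,
    combine_pr_metrics,
    parse_trials,
    pr_runs,
    rolling_choice,
    session_metrics,
    simulate_session,
    win_stay_lose_stay,
)
from .conftest import trials_frame


def make_log(rows, task="bandit_100_0", mouse="m1", sex="F", day=1):
    ev = pd.DataFrame(rows, columns=["time_s", "event", "active_side", "block_index"])
    return SessionLog(mouse, sex, task, day, ev)


class TestParseTrials:
    def test_two_rewarded_left_pokes(self):
        log = make_log(
            [
                (1.0, "poke_left", "left", 0),
                (1.1, "pellet", "left", 0),
                (5.0, "retrieval", "left", 0),
                (9.0, "poke_left", "left", 0),
                (9.1, "pellet", "left", 0),
                (12.0, "retrieval", "left", 0),
            ]
        )
        tr = parse_trials(log)
        assert len(tr) == 2
        assert (tr["choice"] == "left").all()
        assert (tr["outcome"] == "win").all()
        assert tr["retrieval_time_s"].tolist() == [pytest.approx(3.9), pytest.approx(2.9)]

    def test_timeout_then_win_sequence(self):
        log = make_log(
            [
                (1.0, "poke_right", "left", 0),
                (20.0, "poke_left", "left", 0),
                (20.1, "pellet", "left", 0),
                (25.0, "retrieval", "left", 0),
            ]
        )
        tr = parse_trials(log)
        assert tr["choice"].tolist() == ["right", "left"]
        assert tr["outcome"].tolist() == ["loss", "win"]

    def test_pokes_during_timeout_excluded_from_trials(self):
        log = make_log(
            [
                (1.0, "poke_right", "left", 0),   # loss -> timeout till 11.0
                (5.0, "poke_left", "left", 0),    # blocked
                (30.0, "poke_left", "left", 0),
                (30.1, "pellet", "left", 0),
                (33.0, "retrieval", "left", 0),
            ]
        )
        tr = parse_trials(log)
        assert len(tr) == 2
        assert tr["outcome"].tolist() == ["loss", "win"]

    def test_poke_with_unretrieved_pellet_blocked(self):
        log = make_log(
            [
                (1.0, "poke_left", "left", 0),
                (1.1, "pellet", "left", 0),
                (2.0, "poke_left", "left", 0),    # well still loaded
                (5.0, "retrieval", "left", 0),
            ]
        )
        assert len(parse_trials(log)) == 1

    def test_simulated_session_conserves_trials(self, bandit_session):
        assert len(parse_trials(bandit_session)) == 300

    def test_invalid_log_rejected(self):
        log = make_log([(1.0, "retrieval", "left", 0)])
        with pytest.raises(ValueError, match="invalid log"):
            parse_trials(log)


class TestWinStayLoseStay:
    def test_hand_enumerated_example(self):
        tr = trials_frame("LLRR".replace("L", "left,").replace("R", "right,").rstrip(",").split(","),
                          ["win", "loss", "win", "win"])
        ws, ls = win_stay_lose_stay(tr)
        assert ws == 1.0  # wins at t=0 (stay) and t=2 (stay); t=3 has no successor
        assert ls == 0.0  # the single loss was followed by a switch

    def test_all_win_all_left(self):
        tr = trials_frame(["left"] * 5, ["win"] * 5)
        ws, ls = win_stay_lose_stay(tr)
        assert ws == 1.0
        assert np.isnan(ls)  # no post-loss transitions: missing, not zero

    def test_fewer_than_two_trials_gives_missing(self):
        tr = trials_frame(["left"], ["win"])
        assert all(np.isnan(v) for v in win_stay_lose_stay(tr))


class TestSessionMetrics:
    def test_accuracy_over_all_pokes(self):
        rows = []
        t = 0.0
        for i in range(10):
            side = "left" if i < 7 else "right"
            t += 20.0
            rows.append((t, f"poke_{side}", "left", 0))
            if side == "left":
                rows.append((t + 0.1, "pellet", "left", 0))
                rows.append((t + 3.0, "retrieval", "left", 0))
        m = session_metrics(make_log(rows))
        assert m.accuracy == pytest.approx(0.7)
        assert m.pellets == 7
        assert m.pokes == 10

    def test_counts_conserved_on_simulation(self, bandit_session):
        m = session_metrics(bandit_session)
        assert m.pellets == (bandit_session.events["event"] == "pellet").sum()
        assert m.pokes == bandit_session.events["event"].str.startswith("poke").sum()
        assert m.pellets <= m.pokes
        for frac in (m.accuracy, m.win_stay, m.lose_stay):
            assert 0.0 <= frac <= 1.0

    def test_perfect_exploiter_long_run_accuracy(self):
        log = simulate_session(
            WSLSParams(w=1.0, l=1.0, lapse=0.0), BanditConfig(1.0, 0.0),
            n_trials=2100, seed=8,
        )
        m = session_metrics(log)
        assert m.accuracy == pytest.approx(20 / 21, abs=0.02)


class TestPRRuns:
    def pr_log(self, runs, gap_min=31.0):
        """Build a PR1 log earning pellets at ratios 1..q for each q in runs."""
        rows = []
        t = 0.0
        for q in runs:
            for ratio in range(1, q + 1):
                for _ in range(ratio):
                    t += 2.0
                    rows.append((t, "poke_left", "left", 0))
                rows.append((t + 0.1, "pellet", "left", 0))
                rows.append((t + 3.0, "retrieval", "left", 0))
                t += 5.0
            t += gap_min * 60.0
        return make_log(rows, task="pr1")

    def test_single_run_breakpoint(self):
        m = pr_runs(self.pr_log([5]))
        assert m.breakpoints == [5]
        assert m.n_runs == 1
        assert m.median_breakpoint == 5.0

    def test_two_identical_runs_demand_table(self):
        m = pr_runs(self.pr_log([3, 3]))
        assert m.demand_table.values.tolist() == [[1, 2], [2, 2], [3, 2]]

    def test_demand_consumption_sums_to_pellets(self):
        m = pr_runs(self.pr_log([4, 7, 2]))
        assert m.demand_table["pellets"].sum() == m.pellets

    def test_short_gap_does_not_split_runs(self):
        m = pr_runs(self.pr_log([3, 3], gap_min=10.0))
        # 10-minute pauses never reset: a single continuing run, but the
        # second bout restarts poke counting, so ratios continue upward
        assert m.n_runs == 1

    def test_combine_pools_across_days(self):
        a = pr_runs(self.pr_log([3]))
        b = pr_runs(self.pr_log([3]))
        b.day_index = 2
        pooled = combine_pr_metrics([a, b])
        assert pooled.n_runs == 2
        assert pooled.demand_table["pellets"].tolist() == [2, 2, 2]

    def test_non_pr_log_rejected(self, bandit_session):
        with pytest.raises(ValueError, match="pr1"):
            pr_runs(bandit_session)


class TestRollingAndBinned:
    def test_all_left_window(self):
        tr = trials_frame(["left"] * 10, ["win"] * 10)
        rc = rolling_choice(tr, window=10)
        assert rc["frac_left"].tolist() == [1.0]

    def test_alternating_choices(self):
        tr = trials_frame(["left", "right"] * 10, ["win"] * 20)
        rc = rolling_choice(tr, window=10)
        assert np.allclose(rc["frac_left"], 0.5)
        assert len(rc) == 20 - 10 + 1

    def test_fewer_trials_than_window_empty(self):
        tr = trials_frame(["left"] * 3, ["win"] * 3)
        assert len(rolling_choice(tr, window=10)) == 0

    def test_choice_tracks_block_flips(self):
        """Within a block, late-trial accuracy should beat early-trial
        accuracy as the agent re-locks onto the new rewarded side."""
        log = simulate_session(
            WSLSParams(w=0.9, l=0.8, lapse=0.1), BanditConfig(1.0, 0.0),
            n_trials=4000, seed=9,
        )
        tr = parse_trials(log)
        correct = (tr["choice"] == tr["correct_side"]).to_numpy()
        flips = np.flatnonzero(tr["correct_side"].to_numpy()[1:] != tr["correct_side"].to_numpy()[:-1]) + 1
        early, late = [], []
        for start, end in zip(flips[:-1], flips[1:]):
            mid = (start + end) // 2
            early.append(correct[start:mid].mean())
            late.append(correct[mid:end].mean())
        assert np.mean(late) > np.mean(early)

    def test_binned_accuracy_by_hour(self):
        rows = []
        for i in range(4):  # hour 1: 0.5 accuracy
            side = "left" if i % 2 == 0 else "right"
            rows.append((i * 600.0, f"poke_{side}", "left", 0))
        for i in range(4):  # hour 2: perfect
            rows.append((3600.0 + i * 600.0, "poke_left", "left", 0))
        ba = binned_accuracy(make_log(rows), bin_minutes=60)
        assert ba["accuracy"].tolist() == [0.5, 1.0]
        assert ba["n_pokes"].sum() == 8

    def test_empty_bins_flagged_missing(self):
        rows = [(0.0, "poke_left", "left", 0), (7200.0, "poke_left", "left", 0)]
        ba = binned_accuracy(make_log(rows), bin_minutes=60)
        assert len(ba) == 3
        assert np.isnan(ba["accuracy"].iloc[1])
        assert ba["n_pokes"].tolist() == [1, 0, 1]


class TestExclusions:
    def budget_log(self, mouse, task, day, pellets, sex="F"):
        rows = []
        for i in range(pellets):
            t = i * 60.0
            rows.append((t, "poke_left", "left", 0))
            rows.append((t + 0.1, "pellet", "left", 0))
            rows.append((t + 3.0, "retrieval", "left", 0))
        return make_log(rows, task=task, mouse=mouse, sex=sex, day=day)

    def full_battery(self, mouse, pellets=100):
        logs = []
        for task, days in (("bandit_100_0", 3), ("fr1", 1), ("bandit_80_20", 2), ("pr1", 2)):
            for d in range(1, days + 1):
                logs.append(self.budget_log(mouse, task, d, pellets))
        return logs

    def test_low_pellet_day_excluded_with_rule(self):
        logs = self.full_battery("ok") + self.full_battery("hungry", pellets=70)
        kept, report = apply_exclusions(Cohort(logs))
        assert set(kept.mouse_table["mouse_id"]) == {"ok"}
        assert report.loc[report["mouse_id"] == "hungry", "rule"].iloc[0] == "min-pellets"

    def test_missing_task_excluded(self):
        logs = self.full_battery("ok")
        partial = [l for l in self.full_battery("nopr") if l.task != "pr1"]
        for l in partial:
            l.mouse_id = "nopr"
        kept, report = apply_exclusions(Cohort(logs + partial))
        assert set(kept.mouse_table["mouse_id"]) == {"ok"}
        assert report["rule"].iloc[0] == "incomplete-battery"

    def test_clean_cohort_unchanged(self):
        logs = self.full_battery("a") + self.full_battery("b")
        kept, report = apply_exclusions(Cohort(logs))
        assert len(report) == 0
        assert len(kept.sessions) == len(logs)
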