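"""Trial parsing and the per-session behavioural metric battery.

An event log is scanned into per-poke records, splitting pokes into

* *outcome* pokes -- they produced a pellet ("win") or not ("loss": a bandit
  timeout, an FR1 right poke, or a PR1 poke that did not complete the ratio);
* *blocked* pokes -- made while a pellet sat unretrieved in the well or
  during an active timeout; logged but without programmed consequence.

Accuracy is a property of **all** pokes (fraction on the currently active /
high-probability side), whereas win-stay and lose-stay are transition
frequencies over consecutive *outcome* trials, so both views are kept.

"Poke time" is the latency from the previous logged event to the poke, and
"retrieval time" the latency from pellet delivery to retrieval; sessions are
summarised by their medians, which are robust to long home-cage pauses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .event_model import Cohort, SessionLog, TIMEOUT_TASKS, validate_log
from .task_envs import PR1Config

#: full-battery schedule used by the completeness exclusion rule
STUDY_SCHEDULE = (("bandit_100_0", 3), ("fr1", 1), ("bandit_80_20", 2), ("pr1", 2))

TRIAL_COLUMNS = ["index", "choice", "outcome", "correct_side",
                 "poke_time_s", "retrieval_time_s"]


def _scan_pokes(log: SessionLog, timeout_s: float | None = None) -> pd.DataFrame:
    """One row per poke: time, side, blocked flag, outcome, timings."""
    if timeout_s is None:
        timeout_s = 10.0 if log.task in TIMEOUT_TASKS else 0.0
    ev = log.events
    times = ev["time_s"].to_numpy()
    kinds = ev["event"].to_numpy()
    sides = ev["active_side"].to_numpy()

    # retrieval latency for each pellet event
    pellet_rt: dict[int, float] = {}
    pending = None
    for i, kind in enumerate(kinds):
        if kind == "pellet":
            pending = i
        elif kind == "retrieval" and pending is not None:
            pellet_rt[pending] = times[i] - times[pending]
            pending = None

    rows = []
    well = False
    timeout_until = -np.inf
    prev_time = None
    n = len(kinds)
    for i, kind in enumerate(kinds):
        t = times[i]
        if kind == "pellet":
            well = True
        elif kind == "retrieval":
            well = False
        if not kind.startswith("poke_"):
            prev_time = t
            continue
        side = "left" if kind == "poke_left" else "right"
        blocked = well or t < timeout_until
        win = False
        rt = np.nan
        if not blocked:
            j = i + 1
            while j < n and not kinds[j].startswith("poke_") and kinds[j] != "pellet":
                j += 1
            if j < n and kinds[j] == "pellet":
                win = True
                rt = pellet_rt.get(j, np.nan)
            elif timeout_s > 0:
                timeout_until = t + timeout_s
        rows.append(
            (t, side, blocked, win, sides[i],
             np.nan if prev_time is None else t - prev_time, rt)
        )
        prev_time = t
    return pd.DataFrame(
        rows,
        columns=["time_s", "choice", "blocked", "win", "correct_side",
                 "poke_time_s", "retrieval_time_s"],
    )


def parse_trials(log: SessionLog, timeout_s: float | None = None) -> pd.DataFrame:
    """Parse a log into outcome trials (one row per non-blocked poke).

    Returns a DataFrame with columns ``index, choice, outcome, correct_side,
    poke_time_s, retrieval_time_s``, ordered by time.  ``timeout_s`` defaults
    to the study value (10 s) for bandit tasks and 0 otherwise.  The log must
    pass :func:`validate_log`.
    """
    issues = validate_log(log)
    if issues:
        raise ValueError(f"invalid log ({len(issues)} issues): {issues[:3]}")
    pokes = _scan_pokes(log, timeout_s)
    tr = pokes.loc[~pokes["blocked"]].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "index": np.arange(len(tr)),
            "choice": tr["choice"],
            "outcome": np.where(tr["win"], "win", "loss"),
            "correct_side": tr["correct_side"],
            "poke_time_s": tr["poke_time_s"],
            "retrieval_time_s": tr["retrieval_time_s"],
        }
    )
    return out


def win_stay_lose_stay(trials: pd.DataFrame) -> tuple:
    """Transition frequencies: P(stay | previous win), P(stay | previous loss).

    A transition requires a successor trial, so the session's last trial never
    enters a denominator.  If a condition has no transitions its fraction is
    ``nan`` (missing), never 0.
    """
    if len(trials) < 2:
        return (np.nan, np.nan)
    choice = trials["choice"].to_numpy()
    prev_win = (trials["outcome"].to_numpy() == "win")[:-1]
    stay = choice[1:] == choice[:-1]
    n_w, n_l = int(prev_win.sum()), int((~prev_win).sum())
    ws = float(stay[prev_win].mean()) if n_w else np.nan
    ls = float(stay[~prev_win].mean()) if n_l else np.nan
    return ws, ls


@dataclass
class SessionMetrics:
    mouse_id: str
    sex: str
    task: str
    day_index: int
    pellets: int
    pokes: int
    accuracy: float
    win_stay: float
    lose_stay: float
    median_retrieval_time_s: float
    median_poke_time_s: float
    n_switch_blocks: int


def session_metrics(log: SessionLog, timeout_s: float | None = None) -> SessionMetrics:
    """Compute the per-session summary battery.

    Accuracy is over *all* pokes (blocked included) against the active side
    at poke time; pellet and poke counts are conserved against raw events.
    """
    pokes = _scan_pokes(log, timeout_s)
    trials = pokes.loc[~pokes["blocked"]]
    tr_df = pd.DataFrame(
        {"choice": trials["choice"], "outcome": np.where(trials["win"], "win", "loss")}
    )
    ws, ls = win_stay_lose_stay(tr_df)
    acc = float((pokes["choice"] == pokes["correct_side"]).mean()) if len(pokes) else np.nan
    blocks = log.events["block_index"].to_numpy()
    n_switch = int((np.diff(blocks) != 0).sum()) if len(blocks) else 0
    return SessionMetrics(
        mouse_id=log.mouse_id,
        sex=log.sex,
        task=log.task,
        day_index=log.day_index,
        pellets=int((log.events["event"] == "pellet").sum()),
        pokes=int(len(pokes)),
        accuracy=acc,
        win_stay=ws,
        lose_stay=ls,
        median_retrieval_time_s=float(np.nanmedian(trials["retrieval_time_s"]))
        if trials["retrieval_time_s"].notna().any() else np.nan,
        median_poke_time_s=float(np.nanmedian(pokes["poke_time_s"]))
        if pokes["poke_time_s"].notna().any() else np.nan,
        n_switch_blocks=n_switch,
    )


def metrics_table(cohort: Cohort) -> pd.DataFrame:
    """Tidy metric table: one row per (mouse, task, day)."""
    rows = [vars(session_metrics(log)) for log in cohort.sessions]
    return pd.DataFrame(rows).sort_values(
        ["mouse_id", "task", "day_index"], ignore_index=True
    )


@dataclass
class PRMetrics:
    mouse_id: str
    sex: str
    day_index: int
    pellets: int
    pokes: int
    accuracy: float
    median_breakpoint: float
    n_runs: int
    breakpoints: list
    demand_table: pd.DataFrame  # columns: price, pellets
    flags: list


def pr_runs(log: SessionLog, cfg: PR1Config | None = None) -> PRMetrics:
    """Segment a PR1 log into runs and extract breakpoints and demand.

    Runs are delimited by left-poke gaps exceeding the reset window (30 min);
    within a run the poke requirement for the k-th pellet is reconstructed as
    the number of non-blocked left pokes since the previous pellet.  A run's
    breakpoint is the highest ratio at which it earned a pellet, and the
    demand table counts pellets earned at each price across runs.
    """
    if log.task != "pr1":
        raise ValueError(f"pr_runs expects a pr1 log, got {log.task!r}")
    cfg = cfg or PR1Config()
    pokes = _scan_pokes(log, timeout_s=0.0)
    flags = []

    left = pokes.loc[(pokes["choice"] == "left") & (~pokes["blocked"])].reset_index(drop=True)
    gap_s = cfg.reset_window_min * 60.0
    run_ids = np.zeros(len(left), dtype=int)
    if len(left):
        new_run = np.diff(left["time_s"].to_numpy()) > gap_s
        run_ids[1:] = np.cumsum(new_run)

    breakpoints = []
    price_counts: dict[int, int] = {}
    for _, run in pd.DataFrame(left).groupby(run_ids) if len(left) else []:
        ratio = 0
        count = 0
        best = 0
        for win in run["win"]:
            count += 1
            if win:
                ratio = count
                best = ratio
                price_counts[ratio] = price_counts.get(ratio, 0) + 1
                count = 0
        if best > 0:
            breakpoints.append(best)
    n_pellets = int((log.events["event"] == "pellet").sum())
    if n_pellets == 0:
        flags.append("no-pellets")
    demand = pd.DataFrame(
        sorted(price_counts.items()), columns=["price", "pellets"]
    ) if price_counts else pd.DataFrame({"price": [], "pellets": []}).astype(int)
    acc = float((pokes["choice"] == pokes["correct_side"]).mean()) if len(pokes) else np.nan
    return PRMetrics(
        mouse_id=log.mouse_id,
        sex=log.sex,
        day_index=log.day_index,
        pellets=n_pellets,
        pokes=int(len(pokes)),
        accuracy=acc,
        median_breakpoint=float(np.median(breakpoints)) if breakpoints else np.nan,
        n_runs=len(breakpoints),
        breakpoints=breakpoints,
        demand_table=demand,
        flags=flags,
    )


def combine_pr_metrics(per_day: list) -> PRMetrics:
    """Pool PR1 runs across days of the same mouse (the study's 2-day record)."""
    if not per_day:
        raise ValueError("no PR metrics to combine")
    bps = [b for m in per_day for b in m.breakpoints]
    tables = pd.concat([m.demand_table for m in per_day], ignore_index=True)
    demand = (
        tables.groupby("price", as_index=False)["pellets"].sum().sort_values("price")
        if len(tables) else tables
    )
    pokes = sum(m.pokes for m in per_day)
    accs = [m.accuracy * m.pokes for m in per_day if not np.isnan(m.accuracy)]
    return PRMetrics(
        mouse_id=per_day[0].mouse_id,
        sex=per_day[0].sex,
        day_index=0,
        pellets=sum(m.pellets for m in per_day),
        pokes=pokes,
        accuracy=float(np.sum(accs) / pokes) if pokes and accs else np.nan,
        median_breakpoint=float(np.median(bps)) if bps else np.nan,
        n_runs=len(bps),
        breakpoints=bps,
        demand_table=demand.reset_index(drop=True),
        flags=sorted({f for m in per_day for f in m.flags}),
    )


def rolling_choice(trials: pd.DataFrame, window: int = 10) -> pd.DataFrame:
    """Trailing rolling fraction of left choices (the task's choice trace).

    Returns columns ``index`` (index of the window's last trial) and
    ``frac_left``; empty when there are fewer trials than the window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(trials) < window:
        return pd.DataFrame({"index": [], "frac_left": []})
    ind = (trials["choice"] == "left").astype(float)
    frac = ind.rolling(window).mean().dropna()
    return pd.DataFrame(
        {"index": trials["index"].to_numpy()[window - 1:], "frac_left": frac.to_numpy()}
    )


def binned_accuracy(log: SessionLog, bin_minutes: int = 60) -> pd.DataFrame:
    """Poke-based accuracy in fixed time bins (default 1 h, as plotted over 24 h).

    Bins with no pokes appear with ``accuracy = nan`` so gaps are explicit;
    per-bin poke counts sum to the session total.
    """
    if bin_minutes <= 0:
        raise ValueError("bin_minutes must be positive")
    pokes = _scan_pokes(log)
    if not len(pokes):
        return pd.DataFrame({"bin_start_min": [], "accuracy": [], "n_pokes": []})
    width = bin_minutes * 60.0
    b = (pokes["time_s"] // width).astype(int)
    hit = (pokes["choice"] == pokes["correct_side"]).astype(float)
    grouped = pd.DataFrame({"bin": b, "hit": hit}).groupby("bin")["hit"]
    acc = grouped.mean()
    n = grouped.size()
    full = pd.RangeIndex(0, int(b.max()) + 1)
    return pd.DataFrame(
        {
            "bin_start_min": full * bin_minutes,
            "accuracy": acc.reindex(full).to_numpy(),
            "n_pokes": n.reindex(full, fill_value=0).to_numpy(int),
        }
    )


def apply_exclusions(
    cohort: Cohort,
    min_pellets_per_day: int = 75,
    required_schedule=STUDY_SCHEDULE,
) -> tuple:
    """Apply the study's predefined cohort exclusion rules.

    A mouse is dropped if any of its sessions earned fewer than
    ``min_pellets_per_day`` pellets, or if it lacks a full data set of all
    four tasks (every task present, at least the scheduled day count).
    Returns ``(filtered_cohort, report)`` where the report lists one row per
    exclusion with the rule that fired.
    """
    report_rows = []
    excluded = set()
    by_mouse: dict[str, dict[str, int]] = {}
    for log in cohort.sessions:
        by_mouse.setdefault(log.mouse_id, {})
        by_mouse[log.mouse_id][log.task] = by_mouse[log.mouse_id].get(log.task, 0) + 1
        n_pellets = int((log.events["event"] == "pellet").sum())
        if n_pellets < min_pellets_per_day and log.mouse_id not in excluded:
            excluded.add(log.mouse_id)
            report_rows.append(
                {
                    "mouse_id": log.mouse_id,
                    "rule": "min-pellets",
                    "detail": f"{n_pellets} pellets on {log.task} day {log.day_index}"
                    f" (< {min_pellets_per_day})",
                }
            )
    for mouse_id, tasks in by_mouse.items():
        if mouse_id in excluded:
            continue
        missing = [
            task for task, n_days in required_schedule
            if tasks.get(task, 0) < n_days
        ]
        if missing:
            excluded.add(mouse_id)
            report_rows.append(
                {
                    "mouse_id": mouse_id,
                    "rule": "incomplete-battery",
                    "detail": f"missing or short tasks: {missing}",
                }
            )
    kept = [log for log in cohort.sessions if log.mouse_id not in excluded]
    report = pd.DataFrame(report_rows, columns=["mouse_id", "rule", "detail"])
    return Cohort(kept), report
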