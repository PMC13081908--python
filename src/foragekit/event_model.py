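"""Canonical event-log data model for FED3-style operant sessions.

A home-cage pellet dispenser (FED3) logs three things: nose-pokes on the two
ports, pellet deliveries, and pellet retrievals from the food well.  This
module defines the in-memory form of one session (one mouse x one task x one
day), a plain-text CSV dialect for it, a validator, and an adapter for the
native FED3 column set.  Everything downstream -- simulators, the synthetic
cohort, and all analysis stages -- exchanges :class:`SessionLog` objects.

Canonical CSV dialect
---------------------
Comma-separated with a header row naming the columns
``time_s, event, active_side, block_index`` where

* ``time_s`` -- seconds since session start (non-negative, non-decreasing),
* ``event`` -- one of ``poke_left, poke_right, pellet, retrieval``,
* ``active_side`` -- side currently paired with reward (``left``/``right``/``none``),
* ``block_index`` -- bandit contingency block counter (0 for non-bandit tasks).

Session metadata (mouse id, sex, task, day) is stored in leading comment
lines of the form ``# key=value`` so that a file fully round-trips.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_KINDS = ("poke_left", "poke_right", "pellet", "retrieval")
SIDES = ("left", "right", "none")
TASKS = ("bandit_100_0", "fr1", "bandit_80_20", "pr1")
EVENT_COLUMNS = ("time_s", "event", "active_side", "block_index")

#: tasks where unrewarded outcome pokes trigger a timeout
TIMEOUT_TASKS = ("bandit_100_0", "bandit_80_20")


class FormatError(ValueError):
    """Raised when a CSV file does not conform to the event-log dialect."""


class LogValidationError(ValueError):
    """Raised when event rows violate a structural invariant (e.g. time order)."""


@dataclass(eq=False)
class SessionLog:
    """Ordered, timestamped event record for one mouse on one task day.

    ``events`` is a DataFrame with columns ``time_s`` (float),
    ``event``, ``active_side`` (str) and ``block_index`` (int).
    """

    mouse_id: str
    sex: str
    task: str
    day_index: int
    events: pd.DataFrame = field(default_factory=lambda: empty_events())

    def __post_init__(self) -> None:
        ev = pd.DataFrame(self.events).reset_index(drop=True)
        for col in EVENT_COLUMNS:
            if col not in ev.columns:
                raise FormatError(f"events table is missing required column {col!r}")
        ev = ev.loc[:, list(EVENT_COLUMNS)]
        ev["time_s"] = ev["time_s"].astype(float)
        ev["event"] = ev["event"].astype(str)
        ev["active_side"] = ev["active_side"].astype(str)
        ev["block_index"] = ev["block_index"].astype(int)
        self.events = ev

    @property
    def n_events(self) -> int:
        return len(self.events)

    def equals(self, other: "SessionLog") -> bool:
        return (
            self.mouse_id == other.mouse_id
            and self.sex == other.sex
            and self.task == other.task
            and self.day_index == other.day_index
            and self.events.equals(other.events)
        )


def empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": pd.Series(dtype=float),
            "event": pd.Series(dtype=str),
            "active_side": pd.Series(dtype=str),
            "block_index": pd.Series(dtype=int),
        }
    )


@dataclass(eq=False)
class Cohort:
    """A collection of session logs plus the mouse table (id, sex)."""

    sessions: list

    def __post_init__(self) -> None:
        seen = {}
        for s in self.sessions:
            key = (s.mouse_id, s.task, s.day_index)
            if key in seen:
                raise LogValidationError(
                    f"duplicate session for mouse={s.mouse_id} task={s.task} day={s.day_index}"
                )
            seen[key] = True

    @property
    def mouse_table(self) -> pd.DataFrame:
        rows = {}
        for s in self.sessions:
            rows[s.mouse_id] = s.sex
        return pd.DataFrame(
            {"mouse_id": list(rows.keys()), "sex": list(rows.values())}
        )

    def sessions_for(self, mouse_id: str, task: str | None = None) -> list:
        out = [s for s in self.sessions if s.mouse_id == mouse_id]
        if task is not None:
            out = [s for s in out if s.task == task]
        return sorted(out, key=lambda s: (s.task, s.day_index))

    def tasks_of(self, mouse_id: str) -> set:
        return {s.task for s in self.sessions if s.mouse_id == mouse_id}


# ---------------------------------------------------------------------------
# reading / writing the canonical dialect
# ---------------------------------------------------------------------------

_META_RE = re.compile(r"#\s*(\w+)\s*=\s*(.*?)\s*$")


def write_event_csv(log: SessionLog, path: str) -> str:
    """Write ``log`` in the canonical dialect; returns ``path``.

    Two writes of the same log produce byte-identical files.
    """
    buf = io.StringIO()
    buf.write(f"# mouse_id={log.mouse_id}\n")
    buf.write(f"# sex={log.sex}\n")
    buf.write(f"# task={log.task}\n")
    buf.write(f"# day_index={log.day_index}\n")
    log.events.to_csv(buf, index=False, lineterminator="\n")
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())
    return path


def read_event_csv(path: str, **meta_overrides) -> SessionLog:
    """Read a canonical event CSV into a :class:`SessionLog`.

    Metadata is taken from ``# key=value`` comment lines, then from a
    ``<mouse>_<task>_day<d>.csv`` filename pattern, then from keyword
    overrides (``mouse_id=``, ``sex=``, ``task=``, ``day_index=``).

    Raises
    ------
    FormatError
        if a required column is missing (the error names the column).
    LogValidationError
        if timestamps are non-monotone (the error lists offending rows).
    """
    meta: dict = {}
    data_lines = []
    with open(path) as fh:
        for line in fh:
            m = _META_RE.match(line)
            if m and not data_lines:
                meta[m.group(1)] = m.group(2)
            elif line.strip():
                data_lines.append(line)
    if not data_lines:
        raise FormatError(f"{path}: no header row found")

    df = pd.read_csv(io.StringIO("".join(data_lines)), float_precision="round_trip")
    for col in ("time_s", "event", "active_side", "block_index"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    # accept wall-clock datetimes in time_s and convert to relative seconds
    if df["time_s"].dtype == object and len(df):
        ts = pd.to_datetime(df["time_s"], errors="raise")
        df["time_s"] = (ts - ts.iloc[0]).dt.total_seconds()
    df["time_s"] = df["time_s"].astype(float)

    t = df["time_s"].to_numpy()
    bad = np.flatnonzero(np.diff(t) < 0) + 1
    if bad.size:
        raise LogValidationError(
            f"{path}: non-monotone timestamps at row indices {bad.tolist()}"
        )

    fname_meta = _meta_from_filename(os.path.basename(path))
    merged = {**fname_meta, **meta, **{k: v for k, v in meta_overrides.items() if v is not None}}
    return SessionLog(
        mouse_id=str(merged.get("mouse_id", "unknown")),
        sex=str(merged.get("sex", "F")),
        task=str(merged.get("task", "bandit_100_0")),
        day_index=int(merged.get("day_index", 1)),
        events=df,
    )


def _meta_from_filename(name: str) -> dict:
    m = re.match(r"(?P<mouse_id>[^_]+)_(?P<task>[a-z0-9_]+?)_day(?P<day_index>\d+)\.csv$", name)
    return m.groupdict() if m else {}


def validate_log(log: SessionLog) -> list:
    """Check every structural invariant; returns a list of issue strings.

    Validation never raises -- an empty list means the log is clean.  Each
    issue names the violated rule and the offending row where applicable.
    """
    issues = []
    if log.task not in TASKS:
        issues.append(f"task-label: {log.task!r} is not one of {TASKS}")
    if log.sex not in ("F", "M"):
        issues.append(f"sex-label: {log.sex!r} is not 'F' or 'M'")
    if log.day_index < 1:
        issues.append(f"day-index: {log.day_index} is not a positive integer")

    ev = log.events
    t = ev["time_s"].to_numpy()
    if len(t) and t[0] < 0:
        issues.append("time-origin: first timestamp is negative (row 0)")
    for i in (np.flatnonzero(np.diff(t) < 0) + 1):
        issues.append(f"time-order: timestamp decreases at row {i}")
    for i, kind in enumerate(ev["event"]):
        if kind not in EVENT_KINDS:
            issues.append(f"event-kind: unknown event {kind!r} at row {i}")
    for i, side in enumerate(ev["active_side"]):
        if side not in SIDES:
            issues.append(f"active-side: unknown side {side!r} at row {i}")

    # pellet-before-retrieval: a retrieval must be preceded by a pellet with no
    # intervening pellet; a new pellet may not be delivered while one is in the well
    well = False
    for i, kind in enumerate(ev["event"]):
        if kind == "pellet":
            if well:
                issues.append(f"pellet-before-retrieval: pellet at row {i} while well occupied")
            well = True
        elif kind == "retrieval":
            if not well:
                issues.append(f"pellet-before-retrieval: retrieval at row {i} with no pending pellet")
            well = False
    return issues


def split_days(log: SessionLog, day_seconds: float = 86400.0) -> list:
    """Split a multi-day deployment into one :class:`SessionLog` per day.

    Day boundaries are multiples of ``day_seconds`` from the session origin;
    per-day timestamps are re-based to the day start.
    """
    if log.n_events == 0:
        return [log]
    day = (log.events["time_s"] // day_seconds).astype(int)
    out = []
    for j, (d, chunk) in enumerate(log.events.groupby(day, sort=True)):
        ev = chunk.copy()
        ev["time_s"] = ev["time_s"] - d * day_seconds
        out.append(
            SessionLog(log.mouse_id, log.sex, log.task, log.day_index + int(d), ev)
        )
    return out


# ---------------------------------------------------------------------------
# native FED3 adapter
# ---------------------------------------------------------------------------

#: default mapping from native FED3 columns onto the canonical schema
FED3_NATIVE_MAP = {
    "timestamp": "MM:DD:YYYY hh:mm:ss",
    "event": "Event",
    "active_side": "Active_Poke",
    "block_pellets": "Block_Pellet_Count",
    "retrieval_time": "Retrieval_Time",
}

_FED3_EVENT_MAP = {"Left": "poke_left", "Right": "poke_right", "Pellet": "pellet"}


def read_fed3_native_csv(path: str, column_map: dict | None = None, **meta) -> SessionLog:
    """Adapter for CSVs in the native FED3 column layout.

    The native format logs one row per poke or pellet with a wall-clock
    timestamp; retrievals are encoded as the ``Retrieval_Time`` latency on
    pellet rows and are expanded here into explicit retrieval events.  The
    column map is configurable because FED3 firmware revisions differ.
    """
    cmap = {**FED3_NATIVE_MAP, **(column_map or {})}
    df = pd.read_csv(path)
    for key in ("timestamp", "event", "active_side"):
        if cmap[key] not in df.columns:
            raise FormatError(f"{path}: missing required column {cmap[key]!r}")
    ts = pd.to_datetime(df[cmap["timestamp"]])
    t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy(float)

    rows = []
    for i in range(len(df)):
        kind = _FED3_EVENT_MAP.get(str(df[cmap["event"]].iloc[i]))
        if kind is None:
            continue
        side = str(df[cmap["active_side"]].iloc[i]).lower()
        side = side if side in SIDES else "none"
        block = 0
        if cmap.get("block_pellets") in df.columns:
            block = int(df[cmap["block_pellets"]].iloc[i])
        rows.append((t[i], kind, side, block))
        if kind == "pellet" and cmap.get("retrieval_time") in df.columns:
            rt = df[cmap["retrieval_time"]].iloc[i]
            if pd.notna(rt):
                rows.append((t[i] + float(rt), "retrieval", side, block))
    ev = pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).sort_values(
        "time_s", kind="stable", ignore_index=True
    )
    return SessionLog(
        mouse_id=str(meta.get("mouse_id", "unknown")),
        sex=str(meta.get("sex", "F")),
        task=str(meta.get("task", "bandit_100_0")),
        day_index=int(meta.get("day_index", 1)),
        events=ev,
    )


def read_cohort_dir(path: str) -> Cohort:
    """Read every ``*.csv`` event log under ``path`` into a :class:`Cohort`."""
    logs = []
    for name in sorted(os.listdir(path)):
        if name.endswith(".csv") and not name.startswith("ground_truth"):
            logs.append(read_event_csv(os.path.join(path, name)))
    if not logs:
        raise FormatError(f"{path}: no event CSV files found")
    return Cohort(logs)
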