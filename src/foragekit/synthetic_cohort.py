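"""Synthetic study generator: a full four-task cohort with known ground truth.

Emulates a cohort of 62 female / 74 male mice completing the study battery
(bandit 100:0 x 3 days, FR1 x 1 day, bandit 80:20 x 2 days, PR1 x 2 days)
so every pipeline stage can be exercised without the animal dataset.

Per-mouse parameters are drawn once per cohort:

* win-stay ``w`` from sex-specific truncated normals on [0.5, 1] with means
  0.82 (M) / 0.771 (F) and SDs 0.072 / 0.086 (the reported per-sex win-stay
  spread read as between-mouse SD);
* lose-shift ``l`` centred at 0.5 and lapse centred at 0.25, both with a
  small invented spread (SD 0.05) since per-mouse variability of these is
  unreported;
* retrieval times log-normal on a seconds scale, shifted faster for males;
* daily pellet budgets per task in the observed ~120-190 pellets/day range
  (session simulation stops once the budget is earned);
* a PR1 bout model (quit-ratio distribution + heavy-tailed pauses), since
  two-choice WSLS behaviour cannot generate progressive-ratio runs; its only
  job is to exercise run/breakpoint/demand analysis with known ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .event_model import Cohort, SessionLog, EVENT_COLUMNS, write_event_csv
from .task_envs import BanditConfig, PR1Config, EnvState, pr1_step, retrieve_pellet
from .wsls_agent import SessionTiming, WSLSParams, simulate_session
from .trial_metrics import STUDY_SCHEDULE

# ------------------------- cohort-level defaults ---------------------------
WIN_STAY_MEAN = {"M": 0.82, "F": 0.771}
WIN_STAY_SD = {"M": 0.072, "F": 0.086}
W_BOUNDS = (0.5, 1.0)
LOSE_SHIFT_MEAN, LOSE_SHIFT_SD = 0.5, 0.05
LAPSE_MEAN, LAPSE_SD = 0.25, 0.05

#: daily pellet budgets per task (per-day means; SEM x sqrt(n) ~ 25 as SD)
PELLET_BUDGET_MEAN = {
    "bandit_100_0": {"M": 179.0, "F": 176.0},
    "fr1": {"M": 187.0, "F": 166.0},
    "bandit_80_20": {"M": 165.0, "F": 174.0},
}
PELLET_BUDGET_SD = 25.0
PELLET_BUDGET_BOUNDS = (110.0, 240.0)

RETRIEVAL_MEDIAN_F = 5.0          # seconds; log-normal location
MALE_SPEED_FACTOR = 0.8           # male retrieval distribution shifted faster
RETRIEVAL_JITTER_SIGMA = 0.25     # per-mouse spread of log-median
RETRIEVAL_SIGMA = 0.6             # within-session log-SD
POKE_GAP_MEDIAN = 90.0            # seconds between events, log-normal median
POKE_GAP_JITTER_SIGMA = 0.25

MEDIAN_QUIT_RATIO_MEAN, MEDIAN_QUIT_RATIO_SD = 9.0, 1.5
QUIT_SIGMA = 0.35                 # log-SD of the per-run quit-ratio draw
# between-run pauses: the per-mouse median scales with its quit ratio so that
# daily intake stays homeostatically stable (~120 pellets/day) whether a mouse
# makes many short runs or few long ones, mirroring the tight intake spread
# alongside variable breakpoints in real cohorts
PAUSE_MEDIAN_MIN, PAUSE_SIGMA = 85.0, 0.5
P_RIGHT_PR_MEAN, P_RIGHT_PR_SD = 0.2, 0.05

TASK_ENVS = {
    "bandit_100_0": lambda: BanditConfig(1.0, 0.0),
    "bandit_80_20": lambda: BanditConfig(0.8, 0.2),
    "fr1": lambda: "fr1",
}


@dataclass
class MouseSpec:
    mouse_id: str
    sex: str
    wsls: WSLSParams
    retrieval_median_s: float
    poke_gap_median_s: float
    daily_pellets: dict            # task -> per-day pellet budget
    median_quit_ratio: float
    quit_sigma: float = QUIT_SIGMA
    pause_median_min: float = PAUSE_MEDIAN_MIN
    pause_sigma: float = PAUSE_SIGMA
    p_right_pr: float = 0.2


def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(n_f: int = 62, n_m: int = 74, seed: int | None = 0) -> list:
    """Draw per-mouse ground-truth parameters for the synthetic study."""
    if n_f < 1 or n_m < 1:
        raise ValueError("need at least one mouse of each sex")
    rng = np.random.default_rng(seed)
    specs = []
    for sex, n in (("F", n_f), ("M", n_m)):
        for i in range(n):
            w = float(_trunc_normal(rng, WIN_STAY_MEAN[sex], WIN_STAY_SD[sex], *W_BOUNDS))
            l = float(_trunc_normal(rng, LOSE_SHIFT_MEAN, LOSE_SHIFT_SD, 0.0, 1.0))
            lam = float(_trunc_normal(rng, LAPSE_MEAN, LAPSE_SD, 0.0, 1.0))
            ret_median = RETRIEVAL_MEDIAN_F * (MALE_SPEED_FACTOR if sex == "M" else 1.0)
            ret_median *= float(np.exp(rng.normal(0.0, RETRIEVAL_JITTER_SIGMA)))
            gap_median = POKE_GAP_MEDIAN * float(np.exp(rng.normal(0.0, POKE_GAP_JITTER_SIGMA)))
            budgets = {
                task: int(_trunc_normal(rng, PELLET_BUDGET_MEAN[task][sex],
                                        PELLET_BUDGET_SD, *PELLET_BUDGET_BOUNDS))
                for task in PELLET_BUDGET_MEAN
            }
            quit_ratio = float(
                _trunc_normal(rng, MEDIAN_QUIT_RATIO_MEAN, MEDIAN_QUIT_RATIO_SD, 6.0, 20.0)
            )
            specs.append(
                MouseSpec(
                    mouse_id=f"{sex.lower()}{i + 1:03d}",
                    sex=sex,
                    wsls=WSLSParams(w=w, l=l, lapse=lam),
                    retrieval_median_s=ret_median,
                    poke_gap_median_s=gap_median,
                    daily_pellets=budgets,
                    median_quit_ratio=quit_ratio,
                    pause_median_min=PAUSE_MEDIAN_MIN * quit_ratio / MEDIAN_QUIT_RATIO_MEAN,
                    p_right_pr=float(_trunc_normal(rng, P_RIGHT_PR_MEAN, P_RIGHT_PR_SD, 0.0, 0.6)),
                )
            )
    return specs


def ground_truth_table(specs: list) -> pd.DataFrame:
    rows = []
    for s in specs:
        rows.append(
            {
                "mouse_id": s.mouse_id,
                "sex": s.sex,
                "w": s.wsls.w,
                "l": s.wsls.l,
                "lapse": s.wsls.lapse,
                "retrieval_median_s": s.retrieval_median_s,
                "poke_gap_median_s": s.poke_gap_median_s,
                "median_quit_ratio": s.median_quit_ratio,
                **{f"budget_{t}": b for t, b in s.daily_pellets.items()},
            }
        )
    return pd.DataFrame(rows)


def _timing_for(spec: MouseSpec) -> SessionTiming:
    return SessionTiming(
        poke_gap_median=spec.poke_gap_median_s,
        retrieval_median=spec.retrieval_median_s,
        retrieval_sigma=RETRIEVAL_SIGMA,
    )


def generate_pr1_session(
    spec: MouseSpec,
    cfg: PR1Config | None = None,
    duration_h: float = 24.0,
    seed: int | np.random.Generator | None = 0,
    day_index: int = 1,
    quit_sampler=None,
    pause_sampler=None,
) -> SessionLog:
    """Simulate one PR1 day with the bout model, through the real schedule.

    Within a run the mouse works to a drawn quit ratio (log-normal around its
    ``median_quit_ratio``), then takes a heavy-tailed pause; pauses longer
    than the reset window end the run (the breakpoint).  Shorter pauses
    resume the same run with a fresh, higher quit target.  ``quit_sampler``
    (rng, current_ratio) and ``pause_sampler`` (rng) are injectable for
    degenerate scenarios (e.g. never quitting, or always resetting).
    """
    cfg = cfg or PR1Config()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration_s = duration_h * 3600.0

    def default_quit(rng, at_least):
        # fresh quit target strictly above the current ratio
        for _ in range(200):
            q = int(round(np.exp(rng.normal(np.log(spec.median_quit_ratio), spec.quit_sigma))))
            if q >= at_least:
                return max(q, 1)
        return at_least

    def default_pause(rng):
        return float(np.exp(rng.normal(np.log(spec.pause_median_min * 60.0), spec.pause_sigma)))

    quit_sampler = quit_sampler or default_quit
    pause_sampler = pause_sampler or default_pause

    state = EnvState()
    rows = []
    t = 0.0
    mu_ret = np.log(spec.retrieval_median_s)
    quit_target = quit_sampler(rng, 1)
    while t < duration_s:
        # decide side: occasional right pokes with no programmed consequence
        if rng.random() < spec.p_right_pr:
            t += float(np.exp(rng.normal(np.log(2.0), 0.5)))
            pr1_step(state, cfg, "right", t)
            rows.append((t, "poke_right", "left", 0))
            continue
        t += float(np.exp(rng.normal(np.log(2.0), 0.5)))
        outcomes = pr1_step(state, cfg, "left", t)
        rows.append((t, "poke_left", "left", 0))
        if "pellet" in outcomes:
            t_p = t + 0.2
            rows.append((t_p, "pellet", "left", 0))
            rt = float(np.exp(rng.normal(mu_ret, RETRIEVAL_SIGMA)))
            t = t_p + max(rt, 0.05)
            rows.append((t, "retrieval", "left", 0))
            retrieve_pellet(state)
            ratio_earned = state.current_ratio - cfg.increment
            if ratio_earned >= quit_target:
                pause = pause_sampler(rng)
                t += pause
                if pause > cfg.reset_window_min * 60.0:
                    quit_target = quit_sampler(rng, 1)
                else:
                    quit_target = quit_sampler(rng, ratio_earned + 1)
            else:
                # short between-pellet rest inside the run
                t += float(np.exp(rng.normal(np.log(45.0), 0.7)))
    ev = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    ev = ev[ev["time_s"] <= duration_s].reset_index(drop=True)
    return SessionLog(spec.mouse_id, spec.sex, "pr1", day_index, ev)


def generate_study(
    specs: list,
    schedule=STUDY_SCHEDULE,
    seed: int | None = 0,
    pr_duration_h: float = 24.0,
) -> tuple:
    """Run every mouse through the scheduled battery.

    Returns ``(Cohort, ground_truth)``.  A single seed fans out through a
    ``SeedSequence`` so each (mouse, task, day) stream is independent and the
    whole study is reproducible.
    """
    ss = np.random.SeedSequence(seed)
    mouse_seeds = ss.spawn(len(specs))
    logs = []
    for spec, mouse_ss in zip(specs, mouse_seeds):
        n_sessions = sum(n for _, n in schedule)
        session_seeds = iter(mouse_ss.spawn(n_sessions))
        for task, n_days in schedule:
            for day in range(1, n_days + 1):
                rng = np.random.default_rng(next(session_seeds))
                if task == "pr1":
                    logs.append(
                        generate_pr1_session(spec, duration_h=pr_duration_h,
                                             seed=rng, day_index=day)
                    )
                else:
                    env = TASK_ENVS[task]()
                    logs.append(
                        simulate_session(
                            spec.wsls, env,
                            target_pellets=spec.daily_pellets[task],
                            seed=rng,
                            timing=_timing_for(spec),
                            mouse_id=spec.mouse_id,
                            sex=spec.sex,
                            day_index=day,
                        )
                    )
    return Cohort(logs), ground_truth_table(specs)


def write_study(cohort: Cohort, ground_truth: pd.DataFrame, out_dir: str) -> list:
    """Write one CSV per (mouse, task, day) plus the ground-truth table."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for log in cohort.sessions:
        name = f"{log.mouse_id}_{log.task}_day{log.day_index}.csv"
        paths.append(write_event_csv(log, os.path.join(out_dir, name)))
    gt_path = os.path.join(out_dir, "ground_truth.csv")
    ground_truth.to_csv(gt_path, index=False)
    paths.append(gt_path)
    return paths
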