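"""Win-stay / lose-shift (WSLS) agent with a lapse parameter.

The agent follows a trial-by-trial heuristic: after a rewarded choice it
repeats the same choice ("stay") with probability ``w``; after an unrewarded
choice it switches with probability ``l``.  On a fraction ``lapse`` of trials
it drops the rule entirely and chooses at random, modelling disengagement.
The lapse gate is applied first, which gives the clean closed forms

    P(stay | win)  = (1 - lapse) * w       + lapse / 2
    P(stay | loss) = (1 - lapse) * (1 - l) + lapse / 2

used throughout the test suite as estimator oracles.  Study settings: ``l``
fixed at 0.5, ``lapse`` at 0.25, ``w`` swept over [0.5, 1.0], 100 simulated
mice x 300 trials at each reward-probability pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .event_model import SessionLog, EVENT_COLUMNS
from .task_envs import LEFT, RIGHT, BanditConfig, EnvState, bandit_step, fr1_step, retrieve_pellet

#: reward-probability pairs of the study's model sweep
STUDY_PAIRS = ((1.0, 0.0), (0.9, 0.1), (0.8, 0.2), (0.7, 0.3), (0.6, 0.4))
STUDY_W_GRID = tuple(np.round(np.arange(0.5, 1.0001, 0.05), 3))
STUDY_N_AGENTS = 100
STUDY_N_TRIALS = 300


@dataclass
class WSLSParams:
    w: float = 0.8       # win-stay probability
    l: float = 0.5       # lose-shift probability
    lapse: float = 0.25  # probability of a uniform random choice

    def __post_init__(self) -> None:
        for name in ("w", "l", "lapse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class AgentState:
    last_choice: str | None = None   # None only before the first trial
    last_outcome: str | None = None  # "win" / "loss" / None


def stay_after_win_prob(params: WSLSParams) -> float:
    """Closed-form marginal probability of repeating a rewarded choice."""
    return (1.0 - params.lapse) * params.w + params.lapse / 2.0


def stay_after_loss_prob(params: WSLSParams) -> float:
    """Closed-form marginal probability of repeating an unrewarded choice."""
    return (1.0 - params.lapse) * (1.0 - params.l) + params.lapse / 2.0


def estimate_w(win_stay: float, lapse: float = 0.25) -> float:
    """Invert the stay-after-win closed form to recover the agent's ``w``."""
    return float(np.clip((win_stay - lapse / 2.0) / (1.0 - lapse), 0.0, 1.0))


def wsls_choose(params: WSLSParams, state: AgentState, rng: np.random.Generator) -> str:
    """Draw one choice.  Lapse gate first, then the WSLS rule.

    Before any outcome history exists the choice is uniform random.
    """
    if state.last_choice is None or rng.random() < params.lapse:
        return LEFT if rng.random() < 0.5 else RIGHT
    other = RIGHT if state.last_choice == LEFT else LEFT
    if state.last_outcome == "win":
        return state.last_choice if rng.random() < params.w else other
    return other if rng.random() < params.l else state.last_choice


class _TrialSim:
    """Shared agent-environment trial loop for bandit and FR1 sessions."""

    def __init__(self, params: WSLSParams, env, rng: np.random.Generator):
        self.params = params
        self.env = env  # BanditConfig, or the string "fr1"
        self.rng = rng
        self.agent = AgentState()
        self.state = EnvState()

    def step(self, t: float):
        """One outcome trial: returns (choice, win, high_before, block_before)."""
        high, block = self.state.high_side, self.state.block_index
        choice = wsls_choose(self.params, self.agent, self.rng)
        if self.env == "fr1":
            outcome = fr1_step(self.state, choice, t)
            high, block = LEFT, 0
        else:
            outcome = bandit_step(self.state, self.env, choice, t, self.rng)
        if outcome == "blocked":  # cannot happen: the well is cleared each trial
            raise RuntimeError("trial simulator produced a blocked poke")
        win = outcome == "pellet"
        if win:
            retrieve_pellet(self.state)
        self.agent.last_choice = choice
        self.agent.last_outcome = "win" if win else "loss"
        return choice, win, high, block


def _simulate_trials(
    params: WSLSParams,
    env,
    rng: np.random.Generator,
    n_trials: int | None = None,
    target_pellets: int | None = None,
    max_trials: int = 20000,
):
    """Run the trial loop without timing; returns (choices, wins, highs) arrays.

    Stops after ``n_trials`` trials or once ``target_pellets`` pellets have
    been earned (whichever is given), with a hard cap of ``max_trials``.
    """
    if n_trials is None and target_pellets is None:
        raise ValueError("give n_trials or target_pellets")
    sim = _TrialSim(params, env, rng)
    choices, wins, highs = [], [], []
    pellets = 0
    t = 0.0
    while True:
        if n_trials is not None and len(choices) >= n_trials:
            break
        if target_pellets is not None and pellets >= target_pellets:
            break
        if len(choices) >= max_trials:
            break
        choice, win, high, _ = sim.step(t)
        choices.append(choice == LEFT)
        wins.append(win)
        highs.append(high == LEFT)
        pellets += win
        t += 60.0  # nominal spacing; past any timeout
    return (
        np.asarray(choices, dtype=bool),
        np.asarray(wins, dtype=bool),
        np.asarray(highs, dtype=bool),
    )


@dataclass
class SessionTiming:
    """Log-normal event-timing model for simulated sessions (units: seconds).

    ``poke_gap_median`` is the latency from the previous event to the next
    poke -- the quantity recovered downstream as "poke time".
    """

    poke_gap_median: float = 90.0
    poke_gap_sigma: float = 0.9
    retrieval_median: float = 5.0
    retrieval_sigma: float = 0.6
    dispense_delay: float = 0.2


def simulate_session(
    params: WSLSParams,
    env,
    n_trials: int | None = None,
    seed: int | np.random.Generator | None = None,
    *,
    target_pellets: int | None = None,
    timing: SessionTiming | None = None,
    mouse_id: str = "sim",
    sex: str = "F",
    day_index: int = 1,
) -> SessionLog:
    """Simulate one WSLS session and return it as a :class:`SessionLog`.

    ``env`` is a :class:`BanditConfig` or the string ``"fr1"``.  Identical
    ``(params, env, seed)`` produce identical logs.  Inter-trial gaps are
    drawn after any timeout has elapsed, so the emitted log contains no
    blocked pokes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    timing = timing or SessionTiming()
    sim = _TrialSim(params, env, rng)
    cfg_timeout = 0.0 if env == "fr1" else env.timeout_s
    task = "fr1" if env == "fr1" else env.task_name

    rows = []
    t = 0.0
    pellets = 0
    n_done = 0
    mu_gap = np.log(timing.poke_gap_median)
    mu_ret = np.log(timing.retrieval_median)
    while True:
        if n_trials is not None and n_done >= n_trials:
            break
        if target_pellets is not None and pellets >= target_pellets:
            break
        if n_done >= 20000:
            break
        gap = float(np.exp(rng.normal(mu_gap, timing.poke_gap_sigma)))
        t += max(gap, 0.05)
        choice, win, high, block = sim.step(t)
        rows.append((t, f"poke_{choice}", high, block))
        if win:
            t_p = t + timing.dispense_delay
            rows.append((t_p, "pellet", sim.state.high_side, sim.state.block_index))
            rt = float(np.exp(rng.normal(mu_ret, timing.retrieval_sigma)))
            t = t_p + max(rt, 0.05)
            rows.append((t, "retrieval", sim.state.high_side, sim.state.block_index))
            pellets += 1
        else:
            t += cfg_timeout  # next poke gap starts after the timeout window
        n_done += 1
    ev = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    return SessionLog(mouse_id=mouse_id, sex=sex, task=task, day_index=day_index, events=ev)


def model_sweep(
    w_grid=STUDY_W_GRID,
    pairs=STUDY_PAIRS,
    n_agents: int = STUDY_N_AGENTS,
    n_trials: int = STUDY_N_TRIALS,
    l: float = 0.5,
    lapse: float = 0.25,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Sweep win-stay values across reward-probability pairs.

    Returns one row per (pair, w) with the mean trial-level accuracy
    (fraction of choices on the high side) and mean parsed win-stay across
    agents.  Defaults reproduce the study sweep.
    """
    if not len(w_grid) or not len(pairs):
        raise ValueError("w_grid and pairs must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for p_hi, p_lo in pairs:
        cfg = BanditConfig(p_hi=p_hi, p_lo=p_lo)
        for w in w_grid:
            params = WSLSParams(w=float(w), l=l, lapse=lapse)
            accs, n_stay, n_win_trans = [], 0, 0
            for _ in range(n_agents):
                choices, wins, highs = _simulate_trials(params, cfg, rng, n_trials=n_trials)
                accs.append(np.mean(choices == highs))
                prev_win = wins[:-1]
                n_win_trans += int(prev_win.sum())
                n_stay += int((choices[1:] == choices[:-1])[prev_win].sum())
            rows.append(
                {
                    "p_hi": p_hi,
                    "p_lo": p_lo,
                    "w": float(w),
                    "mean_accuracy": float(np.mean(accs)),
                    "mean_win_stay": n_stay / n_win_trans if n_win_trans else np.nan,
                    "n_agents": n_agents,
                    "n_trials": n_trials,
                }
            )
    return pd.DataFrame(rows)


def fit_lapse(
    observed: pd.DataFrame,
    env: BanditConfig,
    lapse_grid=tuple(np.round(np.arange(0.0, 0.51, 0.05), 2)),
    w_grid=STUDY_W_GRID,
    l: float = 0.5,
    n_agents: int = 50,
    n_trials: int = STUDY_N_TRIALS,
    seed: int | None = 0,
):
    """Grid-search the lapse value that best matches observed behaviour.

    ``observed`` needs columns ``win_stay`` and ``accuracy`` (one row per
    mouse).  For each candidate lapse the modelled (win-stay, accuracy) curve
    over ``w_grid`` is simulated and the objective is the mean squared
    distance from each observed point to its nearest curve point.  Returns
    ``(best_lapse, objective_table)``.  The objective is an artifact choice:
    the original fitting criterion is not specified beyond "fit to data".
    """
    results = []
    for lam in lapse_grid:
        sweep = model_sweep(
            w_grid=w_grid, pairs=[(env.p_hi, env.p_lo)], n_agents=n_agents,
            n_trials=n_trials, l=l, lapse=float(lam), seed=seed,
        )
        curve = sweep[["mean_win_stay", "mean_accuracy"]].to_numpy()
        pts = observed[["win_stay", "accuracy"]].to_numpy()
        d2 = ((pts[:, None, :] - curve[None, :, :]) ** 2).sum(axis=2).min(axis=1)
        results.append({"lapse": float(lam), "objective": float(d2.mean())})
    table = pd.DataFrame(results)
    best = float(table.loc[table["objective"].idxmin(), "lapse"])
    return best, table
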