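"""Deterministic state machines for the four home-cage task schedules.

Each task is a pure step function ``(state, config, action, time) -> outcome``
operating on a small mutable :class:`EnvState`.  The schedules:

* **Bandit p_hi:p_lo** -- two nose-pokes; the high side rewards with
  probability ``p_hi``, the low side with ``p_lo``.  Unrewarded outcome pokes
  start a 10 s timeout.  The high side flips every ``block_size`` pellets.
* **FR1** -- the left poke always delivers a pellet; the right poke has no
  programmed consequence and no timeout follows retrieval.
* **PR1 (resetting)** -- pellet ``n`` costs ``n`` left pokes; 30 minutes of
  left-poke silence resets the requirement to 1 (a "breakpoint").

Across all tasks a new pellet cannot be earned until the previous one is
retrieved from the well; such pokes (and pokes during a timeout) are
*blocked*: they are logged but produce no outcome and leave the schedule
untouched.  Blocked pokes do not re-arm an active timeout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LEFT, RIGHT = "left", "right"


@dataclass
class BanditConfig:
    """Two-armed bandit schedule parameters (study values: B=20, T=10 s)."""

    p_hi: float = 1.0
    p_lo: float = 0.0
    block_size: int = 20
    timeout_s: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_lo < self.p_hi <= 1.0):
            raise ValueError("require 0 <= p_lo < p_hi <= 1")
        if self.block_size < 1 or self.timeout_s < 0:
            raise ValueError("require block_size >= 1 and timeout_s >= 0")

    @property
    def task_name(self) -> str:
        return "bandit_100_0" if self.p_hi == 1.0 and self.p_lo == 0.0 else "bandit_80_20"


@dataclass
class PR1Config:
    """Resetting progressive-ratio parameters (study values: +1/pellet, 30 min)."""

    increment: int = 1
    reset_window_min: float = 30.0

    def __post_init__(self) -> None:
        if self.increment < 1 or self.reset_window_min <= 0:
            raise ValueError("require increment >= 1 and reset_window_min > 0")


@dataclass
class EnvState:
    """Schedule bookkeeping shared by the three step functions."""

    high_side: str = LEFT
    pellets_in_block: int = 0
    current_ratio: int = 1
    pokes_toward_ratio: int = 0
    pellet_in_well: bool = False
    timeout_until: float | None = None
    last_left_poke_time: float | None = None
    block_index: int = 0

    def blocked(self, t: float) -> bool:
        return self.pellet_in_well or (
            self.timeout_until is not None and t < self.timeout_until
        )


def bandit_step(
    state: EnvState,
    cfg: BanditConfig,
    action: str,
    t: float,
    rng: np.random.Generator,
) -> str:
    """Advance the bandit schedule by one poke; returns the outcome.

    Outcomes: ``pellet`` | ``timeout`` | ``blocked``.  ``state`` is mutated in
    place.  Exactly one uniform variate is consumed per reward decision, so
    identical seeds give bit-identical sessions.
    """
    if state.blocked(t):
        return "blocked"
    p = cfg.p_hi if action == state.high_side else cfg.p_lo
    if rng.random() < p:
        state.pellet_in_well = True
        state.pellets_in_block += 1
        if state.pellets_in_block >= cfg.block_size:
            # contingency switch fires on the B-th pellet, before the next poke
            state.high_side = RIGHT if state.high_side == LEFT else LEFT
            state.pellets_in_block = 0
            state.block_index += 1
        return "pellet"
    state.timeout_until = t + cfg.timeout_s
    return "timeout"


def fr1_step(state: EnvState, action: str, t: float) -> str:
    """Fixed-ratio-1: left poke -> pellet; right poke -> no consequence."""
    if action == LEFT and state.pellet_in_well:
        return "blocked"
    if action == RIGHT:
        return "none"
    state.pellet_in_well = True
    return "pellet"


def pr1_step(state: EnvState, cfg: PR1Config, action: str, t: float) -> list:
    """Resetting progressive ratio; returns the list of emitted outcomes.

    The reset rule is evaluated lazily at the next left poke: if more than
    ``reset_window_min`` minutes have passed since the previous left poke, a
    ``reset`` marker is emitted (the run's breakpoint, retroactively) and the
    requirement returns to 1 before the poke is processed.  Possible outcome
    sequences: ``[pellet]``, ``[none]``, ``[blocked]``, ``[reset, ...]``.
    """
    if action == RIGHT:
        return ["none"]
    out = []
    if (
        state.last_left_poke_time is not None
        and t - state.last_left_poke_time > cfg.reset_window_min * 60.0
    ):
        state.current_ratio = 1
        state.pokes_toward_ratio = 0
        out.append("reset")
    state.last_left_poke_time = t
    if state.pellet_in_well:
        out.append("blocked")
        return out
    state.pokes_toward_ratio += 1
    if state.pokes_toward_ratio >= state.current_ratio:
        state.pellet_in_well = True
        state.pokes_toward_ratio = 0
        state.current_ratio += cfg.increment
        out.append("pellet")
    else:
        out.append("none")
    return out


def retrieve_pellet(state: EnvState) -> None:
    """Clear the food well (the animal retrieved the pellet)."""
    state.pellet_in_well = False
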