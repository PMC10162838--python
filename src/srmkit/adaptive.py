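"""Adaptive threshold procedures.

Two procedures drive the battery:

* A two-stage transformed up-down staircase (2-down/1-up with uneven
  steps) for the non-speech tasks.  The stimulus gets harder after two
  consecutive correct responses and easier after one error; ascending
  steps are 1.5x the descending steps measured in the adapted domain
  (log for gap and FM depth, linear dB for modulation depth).  Stage 1
  uses coarse steps for 3 reversals, stage 2 fine steps for 6 more, and
  the threshold is the geometric mean of those last six reversal values.
  With the 1.5 step asymmetry the track equilibrates where
  p^2 * step_down = (1 - p^2) * step_up, i.e. at
  p = sqrt(1.5 / 2.5) ~ 77.5% correct.

* A progressive (method-of-descending-limits) track for the speech task:
  the target is fixed at 65 dB SPL while the two maskers start at 57 dB
  SPL and rise 2 dB every two trials, sweeping the target-to-masker ratio
  from +8 to -10 dB across 20 trials.  The threshold heuristic is simply
  ``errors - 10`` dB TMR: an observer who starts missing once the TMR
  drops below its true threshold accumulates exactly the matching error
  count on this schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "ProgressiveConfig",
    "staircase_update",
    "staircase_threshold",
    "convergence_point",
    "progressive_schedule",
    "progressive_threshold",
]


# ---------------------------------------------------------------------------
# Two-stage 2-down/1-up staircase


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the two-stage 2-down/1-up track.

    In the ``log`` domain the step fields are multiplicative factors > 1
    (e.g. 2**0.5 for the gap task's first stage); in the ``linear`` domain
    they are additive (e.g. 0.5 dB for modulation depth).  Ascending steps
    are ``up_to_down_ratio`` times the descending step in the adapted
    domain: factor**ratio for log, ratio*step for linear.
    """

    start_value: float
    domain: str = "log"  # "log" | "linear"
    stage1_down_step: float = 2.0**0.5
    stage2_down_step: float = 2.0**0.1
    up_to_down_ratio: float = 1.5
    stage1_reversals: int = 3
    stage2_reversals: int = 6
    floor: float = 1e-6
    ceiling: float = float("inf")
    max_trials: int = 200

    def __post_init__(self) -> None:
        if self.domain not in ("log", "linear"):
            raise ValueError(f"domain must be 'log' or 'linear', got {self.domain!r}")
        if self.domain == "log" and not (
            self.stage1_down_step > 1 and self.stage2_down_step > 1
        ):
            raise ValueError("log-domain steps must be factors > 1")
        if self.domain == "linear" and not (
            self.stage1_down_step > 0 and self.stage2_down_step > 0
        ):
            raise ValueError("linear-domain steps must be > 0")
        if self.up_to_down_ratio <= 0:
            raise ValueError("up_to_down_ratio must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "StaircaseConfig":
        return cls(**json.loads(text))


@dataclass
class StaircaseState:
    """Mutable track state; advanced one response at a time."""

    value: float
    n_correct_in_row: int = 0
    stage: int = 1
    reversals: list[float] = field(default_factory=list)
    last_direction: int = 0  # -1 down, +1 up, 0 none yet
    finished: bool = False
    n_trials: int = 0
    hit_trial_cap: bool = False

    @classmethod
    def fresh(cls, config: StaircaseConfig) -> "StaircaseState":
        return cls(value=config.start_value)


def _apply_step(value: float, config: StaircaseConfig, stage: int,
                direction: int) -> float:
    step = config.stage1_down_step if stage == 1 else config.stage2_down_step
    if config.domain == "log":
        factor = step if direction < 0 else step**config.up_to_down_ratio
        new = value / factor if direction < 0 else value * factor
    else:
        delta = step if direction < 0 else step * config.up_to_down_ratio
        new = value - delta if direction < 0 else value + delta
    return float(np.clip(new, config.floor, config.ceiling))


def staircase_update(
    state: StaircaseState, config: StaircaseConfig, correct: bool
) -> StaircaseState:
    """Advance the track by one response (state is mutated and returned).

    Two consecutive correct responses move one descending step and reset
    the counter; one incorrect moves one ascending step.  A change of
    movement direction records the pre-step value as a reversal.  The
    reversal that completes stage 1 still uses stage-1 steps; stage-2
    steps apply from the next movement.  After the sixth stage-2 reversal
    the track is finished.  Values clip at the floor/ceiling; a clipped
    move still counts for direction bookkeeping.
    """
    if state.finished:
        raise RuntimeError("staircase already finished")
    state.n_trials += 1

    direction = 0
    if correct:
        state.n_correct_in_row += 1
        if state.n_correct_in_row >= 2:
            state.n_correct_in_row = 0
            direction = -1
    else:
        state.n_correct_in_row = 0
        direction = +1

    if direction != 0:
        if state.last_direction != 0 and direction != state.last_direction:
            state.reversals.append(state.value)
            total = config.stage1_reversals + config.stage2_reversals
            if len(state.reversals) == config.stage1_reversals:
                state.stage = 2
            if len(state.reversals) >= total:
                state.finished = True
                return state
        state.value = _apply_step(state.value, config, state.stage, direction)
        state.last_direction = direction

    if state.n_trials >= config.max_trials and not state.finished:
        state.finished = True
        state.hit_trial_cap = True
    return state


def staircase_threshold(state: StaircaseState, config: StaircaseConfig) -> float:
    """Geometric mean of the last six (stage-2) reversal values."""
    if not state.finished:
        raise RuntimeError("staircase not finished")
    tail = state.reversals[config.stage1_reversals:]
    if not tail:
        raise RuntimeError(
            "track finished without stage-2 reversals (trial cap hit early)"
        )
    values = np.asarray(tail, dtype=float)
    if np.any(values <= 0):
        raise ValueError("geometric mean requires positive reversal values")
    return float(np.exp(np.mean(np.log(values))))


def convergence_point(up_to_down_ratio: float = 1.5) -> float:
    """Asymptotic proportion correct of the 2-down/1-up rule with uneven
    steps: p = sqrt(ratio / (1 + ratio)); 0.7746 at ratio 1.5."""
    if up_to_down_ratio <= 0:
        raise ValueError("ratio must be positive")
    return float(np.sqrt(up_to_down_ratio / (1.0 + up_to_down_ratio)))


# ---------------------------------------------------------------------------
# Progressive TMR track


@dataclass(frozen=True)
class ProgressiveConfig:
    """Speech-task schedule: fixed target level, rising masker level."""

    target_level_db_spl: float = 65.0
    masker_start_db_spl: float = 57.0
    masker_step_db: float = 2.0
    trials_per_level: int = 2
    n_trials: int = 20

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ProgressiveConfig":
        return cls(**json.loads(text))


def progressive_schedule(config: ProgressiveConfig = ProgressiveConfig()) -> pd.DataFrame:
    """Trial-by-trial masker levels and TMRs.

    Default: 20 trials, masker 57,57,59,59,...,75,75 dB SPL, TMR
    +8,+8,+6,+6,...,-10,-10 dB (10 distinct TMR values).
    """
    trials = np.arange(1, config.n_trials + 1)
    level_idx = (trials - 1) // config.trials_per_level
    masker = config.masker_start_db_spl + config.masker_step_db * level_idx
    tmr = config.target_level_db_spl - masker
    return pd.DataFrame({"trial": trials, "masker_db_spl": masker, "tmr_db": tmr})


def progressive_threshold(n_errors: int, config: ProgressiveConfig = ProgressiveConfig()) -> float:
    """Error-count heuristic: threshold TMR (dB) = errors - n_trials/2."""
    if not 0 <= n_errors <= config.n_trials:
        raise ValueError(f"n_errors must be in [0, {config.n_trials}], got {n_errors}")
    return float(n_errors - config.n_trials // 2)
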