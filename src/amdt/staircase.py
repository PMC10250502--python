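"""Transformed up-down (n-down-1-up) adaptive staircase.

The procedure tracks a stimulus variable (here a modulation depth in dB):
after ``n_down`` consecutive correct answers the value is decremented by the
current step size (the stimulus gets harder), after a single wrong answer it
is incremented.  Such a staircase converges to the stimulus level whose
probability of a correct answer is ``0.5**(1/n_down)`` — 0.794 for the
3-down-1-up variant (Levitt's transformed up-down rules).

Step sizes follow a schedule: ``step_sizes[k]`` is in effect until the
``change_points[k]``-th reversal (or trial, in ``by_trial`` mode) has been
recorded, after which ``step_sizes[k+1]`` applies to subsequent steps.

Bookkeeping conventions
-----------------------
A *reversal* is recorded at the trial where an executed step's direction
differs from the previous executed step's direction; the first executed step
records no reversal.  The schedule advances as soon as the triggering
reversal is recorded, so the new step size applies from the next executed
step onward.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Literal, NamedTuple, Optional

import pandas as pd

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "Reversal",
    "Trial",
    "StaircaseError",
    "init",
    "update",
    "is_finished",
    "current_step",
    "state_to_frame",
]


class StaircaseError(ValueError):
    """Invalid staircase configuration or an update on a finished run."""


class Reversal(NamedTuple):
    trial_index: int   # trial whose executed step flipped direction
    value: float       # value presented at that trial
    step: float        # step size in effect for the flipped step


class Trial(NamedTuple):
    trial_index: int
    value: float       # value presented
    answer: bool


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of an n-down-1-up staircase.

    Parameters
    ----------
    start_value:
        Initial tracked value (dB).
    n_down:
        Consecutive correct answers required to step down (3 here).
    step_sizes:
        Ordered step sizes (dB, all > 0); one more entry than
        ``change_points``.
    change_points:
        Reversal (or trial) counts at which the next step size takes effect.
    schedule_mode:
        Whether ``change_points`` count reversals or trials.
    max_trials, max_reversals:
        Stop rules; at least one must be set.
    min_value, max_value:
        Optional saturation bounds on the tracked value.
    """

    start_value: float
    n_down: int = 3
    n_up: int = 1
    step_sizes: tuple[float, ...] = (1.0, 0.5)
    change_points: tuple[int, ...] = (1,)
    schedule_mode: Literal["by_reversal", "by_trial"] = "by_reversal"
    max_trials: Optional[int] = None
    max_reversals: Optional[int] = None
    min_value: Optional[float] = None
    max_value: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "step_sizes", tuple(float(s) for s in self.step_sizes))
        object.__setattr__(self, "change_points", tuple(int(c) for c in self.change_points))
        if self.n_down < 1:
            raise StaircaseError("n_down must be >= 1")
        if self.n_up != 1:
            raise StaircaseError("only 1-up schedules are supported")
        if len(self.step_sizes) != len(self.change_points) + 1:
            raise StaircaseError(
                f"need len(step_sizes) == len(change_points) + 1, got "
                f"{len(self.step_sizes)} steps and {len(self.change_points)} change points"
            )
        if any(s <= 0 for s in self.step_sizes):
            raise StaircaseError("step sizes must be > 0")
        if list(self.change_points) != sorted(self.change_points) or any(
            c < 1 for c in self.change_points
        ):
            raise StaircaseError("change_points must be increasing positive counts")
        if self.schedule_mode not in ("by_reversal", "by_trial"):
            raise StaircaseError(f"unknown schedule_mode {self.schedule_mode!r}")
        if self.max_trials is None and self.max_reversals is None:
            raise StaircaseError("at least one stop rule (max_trials/max_reversals) required")

    @property
    def smallest_step(self) -> float:
        return min(self.step_sizes)


@dataclass(frozen=True)
class StaircaseState:
    """Immutable snapshot of a staircase run."""

    value: float
    consecutive_correct: int = 0
    trial_index: int = 0
    last_step_direction: Optional[Literal["down", "up"]] = None
    reversals: tuple[Reversal, ...] = ()
    history: tuple[Trial, ...] = ()


def init(config: StaircaseConfig) -> StaircaseState:
    """Fresh state at the configured start value."""
    return StaircaseState(value=config.start_value)


def _schedule_count(state: StaircaseState, config: StaircaseConfig) -> int:
    if config.schedule_mode == "by_reversal":
        return len(state.reversals)
    return state.trial_index


def current_step(state: StaircaseState, config: StaircaseConfig) -> float:
    """Step size in effect given the recorded reversal (or trial) count."""
    idx = bisect.bisect_right(config.change_points, _schedule_count(state, config))
    return config.step_sizes[idx]


def is_finished(state: StaircaseState, config: StaircaseConfig) -> bool:
    """True iff any configured stop rule has been met."""
    if config.max_trials is not None and state.trial_index >= config.max_trials:
        return True
    if config.max_reversals is not None and len(state.reversals) >= config.max_reversals:
        return True
    return False


def _clip(value: float, config: StaircaseConfig) -> float:
    if config.min_value is not None:
        value = max(value, config.min_value)
    if config.max_value is not None:
        value = min(value, config.max_value)
    return value


def update(state: StaircaseState, correct: bool,
           config: StaircaseConfig) -> StaircaseState:
    """Apply one answer and return the next state.

    A correct answer increments the consecutive-correct counter; reaching
    ``n_down`` executes a down step and resets the counter.  A wrong answer
    resets the counter and executes an up step.  Reversal recording and
    schedule advancement follow the module conventions above.
    """
    if is_finished(state, config):
        raise StaircaseError("update() called on a finished staircase")

    presented = state.value
    trial = Trial(state.trial_index, presented, bool(correct))
    step = current_step(state, config)

    direction: Optional[str] = None
    value = state.value
    consecutive = state.consecutive_correct
    if correct:
        consecutive += 1
        if consecutive >= config.n_down:
            value = _clip(value - step, config)
            direction = "down"
            consecutive = 0
    else:
        consecutive = 0
        value = _clip(value + step, config)
        direction = "up"

    reversals = state.reversals
    last_dir = state.last_step_direction
    if direction is not None:
        if last_dir is not None and direction != last_dir:
            reversals = reversals + (Reversal(state.trial_index, presented, step),)
        last_dir = direction

    return StaircaseState(
        value=value,
        consecutive_correct=consecutive,
        trial_index=state.trial_index + 1,
        last_step_direction=last_dir,
        reversals=reversals,
        history=state.history + (trial,),
    )


def state_to_frame(state: StaircaseState, config: StaircaseConfig) -> pd.DataFrame:
    """Tabulate a run: trial_index, value, answer, step, reversal_flag.

    ``step`` is the size in effect when the trial was answered; the table is
    the CSV export format consumed by the convergence metrics.
    """
    reversal_trials = {r.trial_index for r in state.reversals}
    # replay schedule position to recover the step in effect per trial
    rows = []
    replay = init(config)
    for trial in state.history:
        rows.append({
            "trial_index": trial.trial_index,
            "value": trial.value,
            "answer": int(trial.answer),
            "step": current_step(replay, config),
            "reversal_flag": int(trial.trial_index in reversal_trials),
        })
        replay = update(replay, trial.answer, config)
    return pd.DataFrame(rows, columns=["trial_index", "value", "answer", "step", "reversal_flag"])
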