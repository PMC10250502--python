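"""Headless 3-AFC amplitude-modulation detection session.

A trial presents three sequential tone intervals at onsets 0.5, 1.5 and
2.5 s from trial start; one randomly chosen interval carries the
amplitude-modulated target at the staircase's current depth, the other two
are unmodulated tones at the same carrier.  A simulated observer answers
each trial, the staircase updates, and start/end event markers are emitted
at the first-stimulus onset and last-stimulus offset on a deterministic
virtual clock, so entire sessions are reproducible from a seed.

Per condition and repetition block the three target positions are balanced
(each occurs ``reps_per_position`` times in shuffled order); condition order
is shuffled per block.  One staircase per condition persists across blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from . import staircase as sc
from .config import ExperimentConfig
from .observer import PsychometricModel, simulate_answer
from .stimulus import AMToneSpec, MixEntry, mix, synthesize_am_tone

__all__ = [
    "Condition",
    "TrialRecord",
    "Marker",
    "SessionResult",
    "SessionError",
    "VirtualClock",
    "build_condition_plan",
    "trial_timeline",
    "emit_marker",
    "run_trial",
    "run_session",
]

DEFAULT_ONSETS_S = (0.5, 1.5, 2.5)


class SessionError(RuntimeError):
    """Invalid session plan or non-monotonic event timing."""


class Condition(NamedTuple):
    carrier_hz: float
    mod_hz: float


class Marker(NamedTuple):
    label: str
    timestamp_s: float


@dataclass(frozen=True)
class TrialRecord:
    condition: Condition
    trial_index: int            # within the condition's staircase run
    target_position: int        # 1-based interval index
    depth_presented: float      # dB
    answer: bool
    start_s: float              # first-stimulus onset marker
    end_s: float                # last-stimulus offset marker


@dataclass
class SessionResult:
    """Complete log of one simulated participant."""

    participant_id: str
    seed: int
    records: list[TrialRecord]
    markers: list[Marker]
    staircases: dict[Condition, sc.StaircaseState]
    staircase_config: sc.StaircaseConfig
    config_snapshot: dict

    def trials_frame(self) -> pd.DataFrame:
        """Session log table (one row per trial, in presentation order)."""
        step_by = {
            cond: dict(
                zip(
                    (t.trial_index for t in state.history),
                    sc.state_to_frame(state, self.staircase_config)["step"],
                )
            )
            for cond, state in self.staircases.items()
        }
        rev_by = {
            cond: {r.trial_index for r in state.reversals}
            for cond, state in self.staircases.items()
        }
        return pd.DataFrame(
            {
                "participant": self.participant_id,
                "carrier_hz": r.condition.carrier_hz,
                "mod_hz": r.condition.mod_hz,
                "trial_index": r.trial_index,
                "target_position": r.target_position,
                "depth": r.depth_presented,
                "answer": int(r.answer),
                "step": step_by[r.condition][r.trial_index],
                "reversal_flag": int(r.trial_index in rev_by[r.condition]),
                "start_s": r.start_s,
                "end_s": r.end_s,
            }
            for r in self.records
        )

    def markers_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.markers, columns=["label", "timestamp_s"])


class VirtualClock:
    """Deterministic clock advancing by the nominal stimulus timeline."""

    def __init__(self, start_s: float = 0.0) -> None:
        self._now = float(start_s)

    def now(self) -> float:
        return self._now

    def advance(self, dt_s: float) -> None:
        if dt_s < 0:
            raise SessionError("clock cannot run backwards")
        self._now += dt_s


def emit_marker(stream: list[Marker], label: str, timestamp_s: float) -> list[Marker]:
    """Append a labeled event marker; timestamps must be non-decreasing."""
    if stream and timestamp_s < stream[-1].timestamp_s:
        raise SessionError(
            f"marker {label!r} at {timestamp_s} s precedes last marker "
            f"at {stream[-1].timestamp_s} s"
        )
    stream.append(Marker(label, float(timestamp_s)))
    return stream


def trial_timeline(onsets_s: Sequence[float] = DEFAULT_ONSETS_S) -> list[tuple[int, float]]:
    """(interval index, onset in seconds from trial start) for each stimulus."""
    return [(i, float(t)) for i, t in enumerate(onsets_s)]


def build_condition_plan(
    conditions: Sequence[Condition],
    reps_per_position: int,
    rng: np.random.Generator,
    n_positions: int = 3,
) -> list[tuple[Condition, list[int]]]:
    """Shuffled condition order with balanced, shuffled target positions.

    Per condition the returned position sequence contains each of the
    ``n_positions`` target positions exactly ``reps_per_position`` times.
    """
    if len(conditions) == 0:
        raise SessionError("at least one condition is required")
    if reps_per_position < 1:
        raise SessionError("reps_per_position must be >= 1")
    order = list(conditions)
    rng.shuffle(order)
    plan = []
    for cond in order:
        positions = np.repeat(np.arange(1, n_positions + 1), reps_per_position)
        rng.shuffle(positions)
        plan.append((cond, positions.tolist()))
    return plan


def run_trial(
    state: sc.StaircaseState,
    condition: Condition,
    model: PsychometricModel,
    rng: np.random.Generator,
    clock: VirtualClock,
    *,
    staircase_config: sc.StaircaseConfig,
    target_position: int,
    markers: Optional[list[Marker]] = None,
    onsets_s: Sequence[float] = DEFAULT_ONSETS_S,
    stimulus_duration_s: float = 0.5,
    rate: float = 44100.0,
    render_audio: bool = True,
) -> tuple[TrialRecord, sc.StaircaseState]:
    """Run one 3-AFC trial against the simulated observer.

    Builds the three stimulus intervals (the target AM tone at the current
    depth plus unmodulated tones), emits start/end markers, draws the answer
    and updates the staircase.  With ``render_audio=False`` the waveforms are
    not synthesized (the mix schedule and all logged quantities are
    unaffected), which speeds up large logic-only simulations.
    """
    depth = state.value
    trial_start = clock.now()
    n_intervals = len(onsets_s)
    if not 1 <= target_position <= n_intervals:
        raise SessionError(f"target_position must be in 1..{n_intervals}")

    if render_audio:
        entries = []
        for interval, onset in trial_timeline(onsets_s):
            is_target = interval + 1 == target_position
            spec = AMToneSpec(
                carrier_hz=condition.carrier_hz,
                mod_hz=condition.mod_hz if is_target else 0.0,
                depth_db=depth if is_target else 0.0,
                duration_s=stimulus_duration_s,
                rate=rate,
            )
            entries.append(MixEntry(synthesize_am_tone(spec), 0.0, 0, onset))
        mix(entries, n_channels=1, rate=rate,
            duration_s=onsets_s[-1] + stimulus_duration_s)

    start_s = trial_start + onsets_s[0]
    end_s = trial_start + onsets_s[-1] + stimulus_duration_s
    if markers is not None:
        emit_marker(markers, "sound_start", start_s)
        emit_marker(markers, "sound_end", end_s)

    answer = simulate_answer(depth, model, rng)
    new_state = sc.update(state, answer, staircase_config)
    record = TrialRecord(
        condition=condition,
        trial_index=state.trial_index,
        target_position=int(target_position),
        depth_presented=depth,
        answer=answer,
        start_s=start_s,
        end_s=end_s,
    )
    clock.advance(end_s - trial_start)
    return record, new_state


def run_session(config: ExperimentConfig, participant_id: str,
                seed: int) -> SessionResult:
    """Simulate one participant's full session.

    Runs ``session.repetitions`` blocks; in each block every condition is
    presented for ``3 * reps_per_position`` balanced trials, with one
    staircase per condition continuing across blocks until its stop rule.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    sess = config.session
    conditions = [Condition(c.carrier_hz, c.mod_hz) for c in config.conditions]
    n_trials_total = sess.repetitions * config.trials_per_condition_block
    stair_cfg = config.staircase.to_staircase_config(default_max_trials=n_trials_total)
    model = PsychometricModel(
        midpoint=config.observer.midpoint_db,
        std=config.observer.std_db,
        guess_rate=config.observer.guess_rate,
    )

    states = {cond: sc.init(stair_cfg) for cond in conditions}
    records: list[TrialRecord] = []
    markers: list[Marker] = []
    clock = VirtualClock()

    for _ in range(sess.repetitions):
        plan = build_condition_plan(conditions, sess.reps_per_position, rng,
                                    n_positions=len(sess.onsets_s))
        for cond, positions in plan:
            for pos in positions:
                if sc.is_finished(states[cond], stair_cfg):
                    break
                record, states[cond] = run_trial(
                    states[cond], cond, model, rng, clock,
                    staircase_config=stair_cfg,
                    target_position=pos,
                    markers=markers,
                    onsets_s=sess.onsets_s,
                    stimulus_duration_s=sess.stimulus_duration_s,
                    rate=sess.rate_hz,
                    render_audio=sess.render_audio,
                )
                records.append(record)
                clock.advance(sess.inter_trial_gap_s)

    return SessionResult(
        participant_id=str(participant_id),
        seed=int(seed),
        records=records,
        markers=markers,
        staircases=states,
        staircase_config=stair_cfg,
        config_snapshot=config.model_dump(),
    )
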