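"""Shared fixtures and an independent staircase replay oracle."""

from __future__ import annotations

import numpy as np
import pytest

from amdt import PsychometricModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)

@pytest.fixture
def default_model():
    """The reference simulated listener: threshold -9 dB, spread 2 dB."""
    return PsychometricModel(midpoint=-9.0, std=2.0)


def replay_staircase(answers, start, n_down=3, step_sizes=(1.0, 0.5),
                     change_points=(1,), mode="by_reversal"):
    """Plain transcription of the n-down-1-up rules, independent of amdt.

    Returns (trajectory of presented values, reversal trial indices,
    final value).  Used as the brute-force oracle for replay-equivalence
    tests: every rule is applied literally, with no shared code or state
    layout with the implementation under test.
    """
    value = float(start)
    streak = 0
    executed_directions = []   # direction of every executed step, in order
    reversal_trials = []
    trajectory = []
    for trial, answer in enumerate(answers):
        trajectory.append(value)
        # step size currently in effect, from the schedule
        counter = len(reversal_trials) if mode == "by_reversal" else trial
        k = 0
        while k < len(change_points) and counter >= change_points[k]:
            k += 1
        step = step_sizes[k]
        # apply the verbal up-down rules
        stepped = None
        if answer:
            streak += 1
            if streak == n_down:
                value -= step
                streak = 0
                stepped = "down"
        else:
            streak = 0
            value += step
            stepped = "up"
        if stepped is not None:
            executed_directions.append(stepped)
            if len(executed_directions) >= 2 and \
                    executed_directions[-1] != executed_directions[-2]:
                reversal_trials.append(trial)
    return trajectory, reversal_trials, value
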