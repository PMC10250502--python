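"""Simulated listener for amplitude-modulation detection.

The observer answers each trial stochastically from a cumulative-Gaussian
(error-function) psychometric function of modulation depth,

    prob(depth) = 1/2 * [1 + erf((depth - midpoint) / (std * sqrt(2)))],

i.e. a listener whose detection threshold is ``midpoint`` dB with spread
``std`` dB.  An answer is drawn as ``uniform(0, 1) < prob(depth)`` once per
trial.  Combined with an n-down-1-up staircase this yields closed-form
convergence predictions: the staircase equilibrates where the probability of
``n_down`` consecutive correct answers equals 1/2, i.e. at
``prob(depth) = 0.5**(1/n_down)``.

By default the function is used verbatim, without a 1/3 guessing floor for
the three-interval forced-choice geometry; pass ``guess_rate=1/3`` to model a
guessing observer instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf, erfinv

__all__ = [
    "PsychometricModel",
    "prob_correct",
    "simulate_answer",
    "convergence_probability",
    "expected_convergence_depth",
]


@dataclass(frozen=True)
class PsychometricModel:
    """Error-function sigmoid: threshold ``midpoint`` (dB), spread ``std`` (dB).

    ``guess_rate`` lifts the lower asymptote from 0 (default, the model used
    verbatim) to e.g. 1/3 for chance performance in a 3-interval task.
    """

    midpoint: float = -9.0
    std: float = 2.0
    guess_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError(f"std must be > 0, got {self.std}")
        if not 0.0 <= self.guess_rate < 1.0:
            raise ValueError(f"guess_rate must be in [0, 1), got {self.guess_rate}")


def prob_correct(depth: float, model: PsychometricModel) -> float:
    """Probability of a correct answer at a given modulation depth (dB)."""
    base = 0.5 * (1.0 + erf((depth - model.midpoint) / (model.std * math.sqrt(2.0))))
    return model.guess_rate + (1.0 - model.guess_rate) * float(base)


def simulate_answer(depth: float, model: PsychometricModel,
                    rng: np.random.Generator) -> bool:
    """Draw one stochastic answer: ``uniform(0,1) < prob_correct(depth)``."""
    return bool(rng.random() < prob_correct(depth, model))


def convergence_probability(n_down: int) -> float:
    """Targeted probability of a correct answer at staircase equilibrium.

    For an n-down-1-up staircase with equal up and down steps the tracked
    value is stationary where ``p**n_down = 1/2``, hence ``0.5**(1/n_down)``:
    0.5 for 1-down, 0.794 for 3-down.
    """
    if n_down < 1:
        raise ValueError(f"n_down must be >= 1, got {n_down}")
    return 0.5 ** (1.0 / n_down)


def expected_convergence_depth(model: PsychometricModel, n_down: int) -> float:
    """Depth (dB) toward which an n-down-1-up staircase converges.

    Inverts the psychometric function at ``convergence_probability(n_down)``.
    """
    p = convergence_probability(n_down)
    base = (p - model.guess_rate) / (1.0 - model.guess_rate)
    return model.midpoint + model.std * math.sqrt(2.0) * float(erfinv(2.0 * base - 1.0))
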