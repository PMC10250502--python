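"""Experiment configuration: validated blocks, YAML loading, seeds.

The configuration mirrors the structure of the experiment: a list of
conditions (carrier / modulation frequency pairs), a staircase block, an
observer block and a session block.  Validation happens up front through
pydantic models so a malformed file fails before any simulation starts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .staircase import StaircaseConfig

__all__ = [
    "ConditionBlock",
    "StaircaseBlock",
    "ObserverBlock",
    "SessionBlock",
    "ExperimentConfig",
    "load_config",
    "validation_design",
]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class ConditionBlock(_Block):
    carrier_hz: float = Field(gt=0)
    mod_hz: float = Field(gt=0)


class StaircaseBlock(_Block):
    start_value: float = 6.0
    n_down: int = Field(default=3, ge=1)
    step_sizes: tuple[float, ...] = (1.0, 0.5)
    change_points: tuple[int, ...] = (1,)
    schedule_mode: Literal["by_reversal", "by_trial"] = "by_reversal"
    max_trials: Optional[int] = None
    max_reversals: Optional[int] = None
    min_value: Optional[float] = None
    max_value: Optional[float] = None

    def to_staircase_config(self, default_max_trials: Optional[int] = None) -> StaircaseConfig:
        max_trials = self.max_trials
        if max_trials is None and self.max_reversals is None:
            max_trials = default_max_trials
        return StaircaseConfig(
            start_value=self.start_value,
            n_down=self.n_down,
            step_sizes=self.step_sizes,
            change_points=self.change_points,
            schedule_mode=self.schedule_mode,
            max_trials=max_trials,
            max_reversals=self.max_reversals,
            min_value=self.min_value,
            max_value=self.max_value,
        )


class ObserverBlock(_Block):
    midpoint_db: float = -9.0
    std_db: float = Field(default=2.0, gt=0)
    guess_rate: float = Field(default=0.0, ge=0.0, lt=1.0)


class SessionBlock(_Block):
    reps_per_position: int = Field(default=12, ge=1)
    repetitions: int = Field(default=1, ge=1)
    n_participants: int = Field(default=10, ge=1)
    base_seed: int = 1
    onsets_s: tuple[float, ...] = (0.5, 1.5, 2.5)
    stimulus_duration_s: float = Field(default=0.5, gt=0)
    rate_hz: float = Field(default=44100.0, gt=0)
    inter_trial_gap_s: float = Field(default=1.0, ge=0)
    render_audio: bool = True


class ExperimentConfig(_Block):
    conditions: tuple[ConditionBlock, ...] = Field(min_length=1)
    staircase: StaircaseBlock = StaircaseBlock()
    observer: ObserverBlock = ObserverBlock()
    session: SessionBlock = SessionBlock()

    @model_validator(mode="after")
    def _check_timeline(self) -> "ExperimentConfig":
        onsets = self.session.onsets_s
        if list(onsets) != sorted(onsets):
            raise ValueError("stimulus onsets must be increasing")
        return self

    @property
    def trials_per_condition_block(self) -> int:
        """Trials per condition within one repetition block."""
        return len(self.session.onsets_s) * self.session.reps_per_position

    def participant_seed(self, participant_index: int) -> int:
        """One independent stream per participant: base seed + index."""
        return self.session.base_seed + participant_index


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration."""
    payload = yaml.safe_load(Path(path).read_text())
    return ExperimentConfig.model_validate(payload)


def validation_design(base_seed: int = 1) -> ExperimentConfig:
    """The reference 3-AFC validation design.

    Ten simulated participants, four conditions (carrier 400/1000 Hz crossed
    with 5/10 Hz modulation), each condition presented in three repetition
    blocks of 36 balanced trials with one continuing 3-down-1-up staircase
    per condition (start +6 dB, 1 dB steps until the first reversal, then
    0.5 dB), answers drawn from the default error-function observer
    (threshold -9 dB, spread 2 dB).
    """
    return ExperimentConfig(
        conditions=(
            ConditionBlock(carrier_hz=400.0, mod_hz=5.0),
            ConditionBlock(carrier_hz=1000.0, mod_hz=5.0),
            ConditionBlock(carrier_hz=400.0, mod_hz=10.0),
            ConditionBlock(carrier_hz=1000.0, mod_hz=10.0),
        ),
        staircase=StaircaseBlock(),
        observer=ObserverBlock(),
        session=SessionBlock(repetitions=3, base_seed=base_seed, render_audio=False),
    )
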