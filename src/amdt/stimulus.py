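"""Stimulus synthesis, leveling, calibration and multichannel mixing.

All monaural stimuli are carried as :class:`AudioTrack` objects whose samples
are normalized to unit root-mean-square (RMS) amplitude.  Working at unit RMS
makes per-file playback levels composable: a track leveled by ``level_db`` has
RMS ``10**(level_db / 20)`` regardless of its content, so a single measured
calibration offset per output channel maps software levels to dB SPL.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioTrack",
    "AMToneSpec",
    "MixEntry",
    "CalibrationProfile",
    "StimulusError",
    "synthesize_am_tone",
    "normalize_rms",
    "downmix_to_mono",
    "resample",
    "apply_level",
    "mix",
    "calibrate_level",
    "read_wav",
    "write_wav",
]

DEFAULT_RATE = 44100.0
DEFAULT_DURATION_S = 0.5


class StimulusError(ValueError):
    """Invalid stimulus specification, schedule or calibration."""


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class AudioTrack:
    """A monaural sample buffer with its sampling rate.

    Parameters
    ----------
    samples:
        1-D array of dimensionless amplitudes.
    rate:
        Sampling rate in Hz, strictly positive.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise StimulusError("AudioTrack samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise StimulusError("AudioTrack samples must be finite")
        if not self.rate > 0:
            raise StimulusError(f"sampling rate must be > 0, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples)))) if len(self.samples) else 0.0


@dataclass(frozen=True)
class AMToneSpec:
    """Specification of a sinusoidally amplitude-modulated tone.

    ``depth_db`` is the modulation depth, ``20*log10(m)`` for modulation index
    ``m`` in ``(1 + m*sin(2*pi*mod_hz*t))``; 0 dB is full modulation.  For
    waveform synthesis the index is clamped to [0, 1] so the envelope stays
    physical; the depth value itself is not clamped (adaptive procedures may
    track values above 0 dB).
    """

    carrier_hz: float
    mod_hz: float
    depth_db: float
    duration_s: float = DEFAULT_DURATION_S
    rate: float = DEFAULT_RATE

    def __post_init__(self) -> None:
        if not self.carrier_hz > 0:
            raise StimulusError(f"carrier_hz must be > 0, got {self.carrier_hz}")
        if self.mod_hz < 0:
            raise StimulusError(f"mod_hz must be >= 0, got {self.mod_hz}")
        if not self.duration_s > 0:
            raise StimulusError(f"duration_s must be > 0, got {self.duration_s}")
        if not self.rate > 0:
            raise StimulusError(f"rate must be > 0, got {self.rate}")

    @property
    def modulation_index(self) -> float:
        """Synthesis modulation index: ``10**(depth_db/20)`` clamped to [0, 1]."""
        return min(1.0, 10.0 ** (self.depth_db / 20.0))


@dataclass(frozen=True)
class MixEntry:
    """One scheduled signal in a mix: track, level, output channel, onset."""

    track: AudioTrack
    level_db: float = 0.0
    channel: int = 0
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.channel < 0:
            raise StimulusError(f"channel must be >= 0, got {self.channel}")
        if self.onset_s < 0:
            raise StimulusError(f"onset_s must be >= 0, got {self.onset_s}")


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-channel offsets mapping software level to measured SPL.

    ``offset_db[c]`` is the measured SPL minus the nominal software level for
    the calibration signal on channel ``c``; playing a unit-RMS signal at
    software level ``L`` on channel ``c`` then produces ``L + offset_db[c]``
    dB SPL.
    """

    offset_db: Mapping[int, float]
    reference: str = ""

    def __post_init__(self) -> None:
        offsets = {int(c): float(o) for c, o in self.offset_db.items()}
        if not all(np.isfinite(list(offsets.values()))) and offsets:
            raise StimulusError("calibration offsets must be finite")
        object.__setattr__(self, "offset_db", offsets)

    def to_json(self, path: str | Path) -> None:
        payload = {"reference": self.reference,
                   "offset_db": {str(c): o for c, o in self.offset_db.items()}}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationProfile":
        payload = json.loads(Path(path).read_text())
        return cls(offset_db={int(c): float(o) for c, o in payload["offset_db"].items()},
                   reference=payload.get("reference", ""))


def normalize_rms(track: AudioTrack) -> AudioTrack:
    """Scale a track so its RMS equals 1.

    Raises
    ------
    StimulusError
        If the track is silent (all zeros), since no positive scalar can give
        it unit RMS.
    """
    rms = track.rms
    if rms == 0.0:
        raise StimulusError("cannot RMS-normalize an all-zero signal")
    return replace(track, samples=track.samples / rms)


def synthesize_am_tone(spec: AMToneSpec) -> AudioTrack:
    """Synthesize a unit-RMS amplitude-modulated tone.

    The raw waveform is ``(1 + m*sin(2*pi*mod_hz*t)) * sin(2*pi*carrier_hz*t)``
    with ``m = min(1, 10**(depth_db/20))``, then RMS-normalized.  With
    ``mod_hz = 0`` or ``m = 0`` this reduces to a pure carrier tone.
    """
    n = _round_half_away(spec.duration_s * spec.rate)
    t = np.arange(n) / spec.rate
    m = spec.modulation_index
    raw = (1.0 + m * np.sin(2.0 * np.pi * spec.mod_hz * t)) * np.sin(
        2.0 * np.pi * spec.carrier_hz * t
    )
    return normalize_rms(AudioTrack(raw, spec.rate))


def downmix_to_mono(samples: Sequence[Sequence[float]] | np.ndarray,
                    rate: float = DEFAULT_RATE) -> AudioTrack:
    """Sum a (channels, n_samples) buffer into one monaural track."""
    try:
        arr = np.asarray(samples, dtype=np.float64)
    except ValueError as exc:
        raise StimulusError("channels have unequal lengths") from exc
    if arr.ndim == 1:
        arr = arr[np.newaxis, :]
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.dtype == object:
        raise StimulusError("expected a (channels, n_samples) buffer")
    return AudioTrack(arr.sum(axis=0), rate)


def resample(track: AudioTrack, target_rate: float) -> AudioTrack:
    """Band-limited (polyphase) resampling to ``target_rate``.

    Pass-through (bitwise identical) when the rate already matches.  The
    rational rate ratio is approximated to within 1e-6 relative error.
    """
    if not target_rate > 0:
        raise StimulusError(f"target_rate must be > 0, got {target_rate}")
    if target_rate == track.rate:
        return track
    ratio = Fraction(target_rate / track.rate).limit_denominator(10_000)
    out = resample_poly(track.samples, ratio.numerator, ratio.denominator)
    return AudioTrack(out, target_rate)


def apply_level(track: AudioTrack, level_db: float) -> AudioTrack:
    """Scale a track by ``10**(level_db/20)``."""
    return replace(track, samples=track.samples * 10.0 ** (level_db / 20.0))


def mix(entries: Sequence[MixEntry], n_channels: int, rate: float,
        duration_s: float) -> np.ndarray:
    """Mix scheduled entries into a (n_channels, n_samples) buffer.

    Each entry's track is resampled to the output rate if needed, scaled by
    its level, and added to its channel starting at the sample nearest its
    onset.  Mixing is purely additive; unscheduled regions are exactly zero.

    Raises
    ------
    StimulusError
        If an entry's channel is out of range or the entry does not fit
        inside the buffer.
    """
    if n_channels < 1:
        raise StimulusError("n_channels must be >= 1")
    n_samples = _round_half_away(duration_s * rate)
    buf = np.zeros((n_channels, n_samples))
    for i, entry in enumerate(entries):
        if entry.channel >= n_channels:
            raise StimulusError(
                f"entry {i}: channel {entry.channel} out of range for "
                f"{n_channels}-channel output"
            )
        track = resample(entry.track, rate)
        start = _round_half_away(entry.onset_s * rate)
        stop = start + len(track.samples)
        if stop > n_samples:
            raise StimulusError(
                f"entry {i}: onset {entry.onset_s} s + duration "
                f"{track.duration_s:.6g} s overruns the {duration_s} s buffer"
            )
        buf[entry.channel, start:stop] += track.samples * 10.0 ** (entry.level_db / 20.0)
    return buf


def calibrate_level(target_spl: float, channel: int,
                    profile: CalibrationProfile) -> float:
    """Software level that plays at ``target_spl`` dB SPL on ``channel``."""
    if channel not in profile.offset_db:
        raise StimulusError(f"no calibration offset for channel {channel}")
    return target_spl - profile.offset_db[channel]


def read_wav(path: str | Path) -> AudioTrack:
    """Read a WAV file; multichannel content is summed to mono."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    if data.ndim == 2:
        return downmix_to_mono(data.T, float(rate))
    return AudioTrack(data.astype(np.float64), float(rate))


def write_wav(path: str | Path, track: AudioTrack) -> None:
    """Write a track as 32-bit float mono WAV."""
    wavfile.write(str(path), int(round(track.rate)), track.samples.astype(np.float32))
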